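# Default study scenario for `canistr simulate --config`.
#
# Two populations diverged at subdivision theta = 0.08 under the
# Balding-Nichols model: a panmictic wolf-like sample (n = 103) and a larger
# dog-like sample (n = 198) with mild breeding-induced inbreeding.
# 15 autosomal STR loci with 5-26 alleles each.
#
# Optional corruption:
#   null_rates:  map "population:locus" -> hidden null-allele frequency
#   stutter_rate: probability that an adjacent-size heterozygote is
#                 miscalled as a homozygote (applied to every locus)
#   substructure: second-level subdivision inside one population, e.g.
#     substructure: {population: dog, theta: 0.02,
#                    groups: {molossian: 32, samoyed: 66, shepherd: 22,
#                             outbred: 78}}

n_loci: 15
allele_count_range: [5, 26]
ancestral_dirichlet_concentration: 1.0
theta_between: 0.08
fis: {wolf: 0.0, dog: 0.05}
n_per_population: {wolf: 103, dog: 198}
stutter_rate: 0.0
# null_rates: {"dog:L02": 0.1}
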