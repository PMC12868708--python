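"""Why ultra-rare pathogenic *HFE* alleles barely move the risk landscape.

Aggregates the 201 observed copies of the 13 ultra-rare pathogenic
variants into a combined allele frequency and predicts how often they
occur as compound heterozygotes with the common C282Y allele.
"""

from hfemap.datasets import C282Y_MAC_UKB, UKB_TOTAL_ALLELES, ULTRA_RARE_MAC_TOTAL
from hfemap.popgen import aggregate_rare_af, rare_with_c282y_rate

af_rare = aggregate_rare_af([ULTRA_RARE_MAC_TOTAL], UKB_TOTAL_ALLELES)
p_c282y = C282Y_MAC_UKB / UKB_TOTAL_ALLELES
rate, one_in = rare_with_c282y_rate(af_rare, p_c282y)

print(f"combined ultra-rare allele frequency : {af_rare:.1e}")
print(f"C282Y allele frequency               : {p_c282y:.4f}")
print(f"(ultra-rare)/C282Y compound hets     : {rate:.1e}  (one in {one_in})")
print(
    "\nRoughly 1 in 33,000 people carries one ultra-rare pathogenic allele\n"
    "together with C282Y - vanishingly rare next to the ~1/164 C282Y\n"
    "homozygotes, so the geography of risk is set by the two common variants."
)
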