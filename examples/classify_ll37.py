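"""Residue-class composition of the LL-37 antimicrobial peptide.

LL-37's mix of charged, hydrophobic and polar residues underlies its
amphipathic helix and its affinity for lipid aggregates; the net charge
drives the electrostatic attraction to bacterial membranes.
"""

import amphitraj as at

res = at.classify_residues(at.LL37_SEQUENCE)
print(f"sequence ({len(res.sequence)} residues): {res.sequence}")
print(f"charged     {res.percent['charged']:3d} %")
print(f"hydrophobic {res.percent['hydrophobic']:3d} %")
print(f"polar       {res.percent['polar']:3d} %")
print(f"basic fraction of charged: {100 * res.basic_fraction_of_charged:.0f} %")
print(f"net charge at pH 7: {res.net_charge:+d} e")
# The 43/43/14 split with ~69% of charged residues basic gives the +6
# net charge that makes the peptide membrane-seeking.
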