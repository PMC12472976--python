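"""Digest the six packaged study proteins with the reference subtilisin rule.

Prints, per protein, the chain length N, the number of hydrolysed bonds d
and the theoretical degree of hydrolysis DHt = 100*d/(N-1): the fraction
of peptide bonds the simulated digestion cleaves.
"""

from wortpep import SUBTILISIN_RULE, digest, load_fixtures, theoretical_dh

print(f"rule: {SUBTILISIN_RULE.name}  P1={SUBTILISIN_RULE.p1_str}  "
      f"P1' veto={SUBTILISIN_RULE.block_str}\n")
for protein in load_fixtures():
    res = digest(protein, SUBTILISIN_RULE)
    print(f"{protein.id:11s} N={protein.length_aa:3d} d={res.n_cuts:3d} "
          f"DHt={theoretical_dh(res, protein):5.2f}%  "
          f"({len(res.peptides)} peptides)")
print("\nHigher DHt = deeper simulated hydrolysis; the hemp proteins "
      "cleave more deeply than the Q/P-rich barley hordeins.")
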