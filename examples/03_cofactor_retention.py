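"""ATP/NAD(P)H usage vs network size.

Computes per-organism percentages of ATP-consuming (ATP among educts) and
NAD(P)H-utilizing (either side) reactions, then the Spearman correlation
of each percentage with the organism's core reaction count.  In the
synthetic cohort — as in real parasite panels — the smaller an organism's
core metabolism, the larger its ATP-consuming share: a negative rho means
ATP-requiring reactions resist loss during reductive evolution.
"""

from coremetnet import (
    SyntheticStudyTruth,
    cofactor_summaries,
    generate_study,
    size_cofactor_correlation,
)

bundle = generate_study(SyntheticStudyTruth(seed=42))
summaries = cofactor_summaries(list(bundle.reactions), list(bundle.profiles))

print(f"{'organism':>10} {'reactions':>9} {'%ATP':>6} {'%NAD(P)H':>9}")
for s in sorted(summaries, key=lambda s: s.n_reactions):
    print(f"{s.organism_code:>10} {s.n_reactions:>9} "
          f"{s.pct_atp:>6.1f} {s.pct_nad:>9.1f}")

for which in ("atp", "nad"):
    res = size_cofactor_correlation(summaries, which)
    print(f"Spearman rho({which}) = {res.statistic:+.3f}  (p = {res.p_value:.4f})")
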