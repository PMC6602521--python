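"""Solo-mode analysis on a synthetic dataset: peaks only.

The fixture plants a 50-gene target set whose TSSs attract ChIP-seq peaks;
the pipeline classifies the cistrome, scores regulatory potential, and the
mHG enrichment recovers the planted term against 50 random null terms.
"""

from cistromego import FixtureSpec, analyze
from cistromego.fixtures import make_annotation, make_gmt, make_peaks

spec = FixtureSpec(seed=1)  # 5000 genes, 50-gene planted term, background peaks
genes = make_annotation(spec)
rng = spec.rng()
peaks = make_peaks(spec, genes, rng)
sets = make_gmt(spec, genes, rng)

out = analyze(genes, peaks, sets)
report = out["classification"]
print(f"cistrome label : {report.label} (fractions near TSS: "
      + ", ".join(f"{k}={v:.3f}" for k, v in report.fractions.items()) + ")")
print(f"decay distance : {report.chosen_d0:.0f} bp\n")

print("top 3 enriched terms (of those tested):")
for r in out["solo_enrichment"][:3]:
    print(f"  {r.set_id:10s} p = {r.pvalue:10.3g}  FDR = {r.fdr:8.3g}  "
          f"ES = {r.enrichment_score:5.1f}  ({r.b_at_cutoff}/{r.B} members "
          f"above cutoff n* = {r.n_star})")
print()
print("The planted term should lead by many orders of magnitude; null")
print("terms hover near uniform p-values.")
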