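"""Ensemble mode: integrating binding with differential expression.

When a knock-down / perturbation experiment accompanies the ChIP-seq data,
genes are ranked by the product of their binding rank and their
differential-expression rank; genes high on both lists are the most likely
direct targets, which sharpens the enrichment signal.
"""

from cistromego import FixtureSpec, analyze
from cistromego.fixtures import make_annotation, make_dge, make_gmt, make_peaks

# moderate binding signal + strong expression signal on the same 50 genes
spec = FixtureSpec(n_genes=2000, n_null_terms=20, peaks_per_target_lambda=2.0,
                   signal_distance_scale=1000.0, n_background_peaks=8000,
                   seed=1)
genes = make_annotation(spec)
rng = spec.rng()
peaks = make_peaks(spec, genes, rng)
dge = make_dge(spec, genes, rng)
sets = make_gmt(spec, genes, rng)

out = analyze(genes, peaks, sets, dge=dge)

solo = {r.set_id: r.pvalue for r in out["solo_enrichment"]}
ens = {r.set_id: r.pvalue for r in out["ensemble_enrichment"]}
print(f"planted term, solo ranking     : p = {solo['PLANTED1']:.3g}")
print(f"planted term, ensemble ranking : p = {ens['PLANTED1']:.3g}")
print(f"AUROC of adjusted RP vs DE labels: {out['roc'].auc:.3f}")
print()
print("The ensemble p-value is (typically much) smaller: expression")
print("evidence rescues bound-but-noisy targets, and the ROC shows how")
print("well binding alone predicts the expression response.")

top = out["ensemble_table"].head(3)[["gene_id", "rank_rp", "rank_de",
                                     "rank_product", "final_rank"]]
print("\nbest-supported direct targets (rank product):")
print(top.to_string(index=False))
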