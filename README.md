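# peepkit

Individual-level analysis of treatment response in placebo-controlled paired
expression trials, built around **personalized perturbation profiles (PEEPs)**.

The motivating setting is a severe-asthma trial of imatinib (a KIT tyrosine
kinase inhibitor) in which bronchial-epithelium gene expression was measured
before and after treatment in a small treated arm (n = 10) and a placebo arm
(n = 14), with lung function (FEV₁, forced expiratory volume in one second)
as the clinical endpoint. Group-wise statistics struggle at this sample size
and with heterogeneous drug response; peepkit implements the individual-level
alternative end to end:

1. **Paired differential expression** per arm: for each gene, a one-sample
   t-test on per-subject deltas Δ = x(post) − x(pre); Benjamini–Hochberg
   q-values reported alongside nominal p-values.
2. **Placebo-concordance filter**: genes significant (p ≤ 0.05) in *both*
   arms with the same direction of effect are discarded as placebo /
   repeat-measurement effects; the remainder of the treated-arm significant
   genes form the treatment-unique panel.
3. **PEEP construction**: for every treated subject and panel gene,
   z(g) = (x_post(g) − μ_ref(g)) / σ_ref(g) against a control reference
   distribution; genes with |z| ≥ 2 are called perturbed (up or down).
4. **Responder stratification and clustering**: subjects are stratified by
   FEV₁ percent change (strong > 20 %, weak 5–10 %, non-responder < 5 %) and
   their profiles clustered with average-linkage (UPGMA) on Euclidean
   distances; agreement is scored with the adjusted Rand index.
5. **Shared calls and pathway enrichment**: genes commonly repressed (or
   induced) within a stratum are tested against GMT gene-set collections
   with a one-sided hypergeometric over-representation test, conditioning on
   the panel as universe; sets significant in exactly one stratum are
   flagged "unique".
6. **Network proximity**: on a functional protein–protein interaction
   network (HumanNet-style edge list), the *closest-distance* statistic —
   mean over source genes of the minimum hop distance to a target gene set —
   compares how close each stratum's genes sit to a candidate gene family
   (e.g. the Bcl-2 anti-apoptotic family), with optional degree-binned
   permutation z-scores; disease modules (largest connected component of a
   gene set) are extracted the same way.

Because the original patient data are not public, peepkit ships a
first-class **synthetic-trial generator** (`peepkit.synthdata`) that plants a
known repressed gene module in responder subjects, placebo-drift genes in
both arms, stratum-consistent FEV₁ changes, and a network in which the
module sits next to a designated target family — so every stage is testable
against ground truth.

## Worked example

```python
import peepkit as pk
from peepkit.pipeline import RunConfig, run_all

matrix, meta, truth = pk.simulate_trial(pk.TrialDesign(seed=0))
network = pk.simulate_network(truth, seed=0)
collection = pk.simulate_genesets(truth, n_sets=50, seed=0)

pk.write_expression(matrix, "expression.tsv")
pk.write_metadata(meta, "metadata.tsv")
pk.write_network(network, "network.tsv")
pk.write_gmt(collection, "genesets.gmt")

report = run_all(RunConfig(
    expression_path="expression.tsv", metadata_path="metadata.tsv",
    gmt_path="genesets.gmt", network_path="network.tsv",
    target_genes=tuple(sorted(truth.target_set)),
    output_dir="run", seed=0,
))
```

The report for this seed contains (abridged):

```json
{
 "panel_size": 111,
 "n_case_significant": 142,
 "n_placebo_concordant_removed": 31,
 "strata_counts": {"non": 5, "weak": 3, "strong": 2},
 "shared_gene_counts": {"strong_down": 11, "weak_down": 1, "non_down": 0},
 "unique_pathways": [
  {"direction": "down", "set_name": "planted_module_pathway", "stratum": "strong"}
 ],
 "clustering_ari": 0.231,
 "proximity": {
  "disease_module_size": 10,
  "strong_to_target": 2.0,
  "non_to_target": 4.286,
  "strong_closer": true
 }
}
```

Reading it: 142 genes were nominally significant in the treated arm; 31 were
removed as placebo-concordant, leaving a 111-gene panel. The two strong
responders shared 11 repressed genes; those genes hit the planted pathway as
the top enrichment, *uniquely* in the strong stratum, and sit far closer to
the planted target family on the network (mean 2.0 hops) than the
non-responders' perturbed genes do (mean 4.3 hops) — the qualitative
signature the method is designed to expose. Weak and non-responders share
essentially nothing, and the profile clustering only partially recovers the
strata (ARI 0.23): with a −3 SD module effect diluted across a 2/3/5
responder split, per-gene arm-level power is modest (see
`docs/methods.md`).

The same pipeline is available from the shell:

```bash
peepkit simulate --outdir sim --seed 0
peepkit run-all --config run.yaml
peepkit table-check          # Welch t-tests on the bundled baseline table
```

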