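"""Generate the synthetic study dataset and interaction fixtures.

Produces the default study conditions: 1,500 genes x 50 samples (5 age
groups x 10) with 15 planted co-expression modules (sizes 30-120) of which
three are trait-linked; 428 miRNAs x 29 samples with a 19-miRNA abundant
tier; 63 TFs with 20 planted gene partners.  Writes all fixtures under
results/data/.
"""

from pathlib import Path

from thymonet import io, simulate_dataset, emit_interaction_fixtures

OUT = Path(__file__).resolve().parent.parent / "results" / "data"
SEED = 0


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    mrna, mirna, tf, meta, truth = simulate_dataset(seed=SEED)
    io.write_expression_matrix(mrna, OUT / "mrna.tsv")
    io.write_expression_matrix(mirna, OUT / "mirna.tsv")
    io.write_expression_matrix(tf, OUT / "tf.tsv")
    io.write_sample_metadata(meta, OUT / "samples.tsv")
    truth.to_json(OUT / "ground_truth.json")
    tf_target, mirna_tf = emit_interaction_fixtures(truth, n_tf_decoys=30)
    io.write_interaction_table(tf_target, OUT / "tf_target.tsv")
    io.write_interaction_table(mirna_tf, OUT / "mirna_tf.tsv")
    print(f"mRNA: {mrna.n_features} genes x {mrna.n_samples} samples; "
          f"{sum(1 for m in truth.module_of_gene.values() if m)} genes in "
          f"{max(truth.module_of_gene.values())} planted modules")
    print(f"miRNA: {mirna.n_features} x {mirna.n_samples} "
          f"({len(truth.abundant_mirnas)} abundant planted)")
    print(f"TF: {tf.n_features} x {tf.n_samples} "
          f"({len(truth.planted_tf_edges)} planted TF-gene edges)")
    print(f"fixtures written to {OUT}")


if __name__ == "__main__":
    main()
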