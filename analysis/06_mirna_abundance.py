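"""Abundant and differentially expressed miRNA selection.

Places a knee cutoff on each age group's linear-intensity distribution,
selects miRNAs whose group mean reaches the cutoff, and tests all miRNAs for
differential expression across the five groups (raw ANOVA p < 0.01).
"""

from pathlib import Path

import pandas as pd

from thymonet import io, mirna

ROOT = Path(__file__).resolve().parent.parent / "results"
DATA = ROOT / "data"


def main() -> None:
    m = io.read_expression_matrix(DATA / "mirna.tsv")
    meta = io.read_sample_metadata(DATA / "samples.tsv")
    cuts = mirna.knee_cutoffs_per_group(m, meta)
    by_group, union = mirna.abundant_mirnas(m, meta, cuts)
    de = mirna.mirna_anova(m, meta, alpha=0.01)
    pd.DataFrame(
        [{"group": g, "cutoff": round(cuts.cutoffs[g], 1),
          "n_abundant": len(v), "mirnas": ",".join(v)}
         for g, v in by_group.items()]
    ).to_csv(ROOT / "abundant_by_group.tsv", sep="\t", index=False)
    pd.Series(union, name="mirna").to_csv(ROOT / "abundant_union.tsv",
                                          sep="\t", index=False)
    de.to_csv(ROOT / "mirna_anova.tsv", sep="\t", index_label="mirna")
    print("knee cutoffs (linear intensity):",
          {g: round(c, 1) for g, c in cuts.cutoffs.items()})
    print(f"abundant miRNAs per group: "
          f"{ {g: len(v) for g, v in by_group.items()} }; "
          f"union {len(union)} of {m.n_features}")
    in_all = set(union)
    for v in by_group.values():
        in_all &= set(v)
    print(f"{len(in_all)} miRNA(s) abundant in every age group")
    print(f"{int(de['de'].sum())} DE miRNA(s) across groups (p < 0.01)")


if __name__ == "__main__":
    main()
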