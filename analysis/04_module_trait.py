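"""Module-trait association: which modules track which age groups.

Correlates every module eigengene with the gender and age-group indicators,
computes per-gene gene significance (GS) and per-module mean-GS module
significance (MS), and lists the module-trait pairs significant at p < 0.05.
"""

from pathlib import Path

import pandas as pd

from thymonet import RunConfig, io, trait
from thymonet.pipeline import run_network
from thymonet.types import trait_designs

ROOT = Path(__file__).resolve().parent.parent / "results"
DATA = ROOT / "data"


def main() -> None:
    cfg = RunConfig()
    mrna = io.read_expression_matrix(DATA / "mrna.tsv")
    meta = io.read_sample_metadata(DATA / "samples.tsv")
    res = run_network(mrna, cfg)
    mt = trait.module_trait_analysis(mrna, res.eigengenes, res.modules,
                                     trait_designs(meta))
    mt.me_trait_r.to_csv(ROOT / "me_trait_r.tsv", sep="\t",
                         index_label="module")
    mt.me_trait_p.to_csv(ROOT / "me_trait_p.tsv", sep="\t",
                         index_label="module")
    mt.ms.to_csv(ROOT / "module_significance.tsv", sep="\t",
                 index_label="module")
    sig = trait.select_significant_modules(mt, alpha=cfg.alpha_module)
    pd.DataFrame(sig, columns=["module", "trait", "r", "p"]).to_csv(
        ROOT / "significant_modules.tsv", sep="\t", index=False)
    print(f"{len(sig)} significant module-trait pair(s) at "
          f"p < {cfg.alpha_module}:")
    for module, t, r, p in sig:
        print(f"  {module:>12s} ~ {t}: r = {r:+.2f} (p = {p:.4f})")


if __name__ == "__main__":
    main()
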