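"""Group contrasts on mean PC and the PC-behaviour association.

Permutation tests compare drug vs placebo mean PC for each annotation axis
(results/pc_group_tests.csv); a partial Spearman correlation, controlling
for age and sex with both arms pooled, relates load-annotation PC to 3-back
and threat accuracy (results/behavior_association.csv).
"""

import importlib
import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
cfg = importlib.import_module("00_config")

from loadmapper.stats import partial_spearman, permutation_group_test


def main() -> None:
    pc = pd.read_csv(cfg.RESULTS / "pc_summary.csv")
    subjects = pd.read_csv(cfg.RESULTS / "subjects.csv")

    rows = []
    for axis, chunk in pc.groupby("axis"):
        res = permutation_group_test(chunk["mean_pc"], chunk["group"],
                                     n_perm=10_000, seed=cfg.SEED)
        rows.append({"axis": axis, "mph_minus_pla": res.statistic,
                     "p_value": res.p_value})
        print(f"axis={axis}: drug-placebo mean-PC difference "
              f"{res.statistic:+.4f}, p={res.p_value:.4g}")
    pd.DataFrame(rows).to_csv(cfg.RESULTS / "pc_group_tests.csv", index=False)

    load_pc = pc.query("axis == 'load'").merge(subjects, on=["subject", "group"])
    cov = np.column_stack([load_pc["age"],
                           (load_pc["sex"] == "F").astype(float)])
    assoc_rows = []
    for label, col in [("3-back accuracy (high load)",
                        0.5 * (load_pc["acc_3-back_safe"] + load_pc["acc_3-back_threat"])),
                       ("threat accuracy (induced anxiety)",
                        0.5 * (load_pc["acc_1-back_threat"] + load_pc["acc_3-back_threat"]))]:
        res = partial_spearman(load_pc["mean_pc"], col, cov,
                               n_perm=10_000, seed=cfg.SEED)
        assoc_rows.append({"behaviour": label, "rho": res.rho, "n": res.n,
                           "p_value": res.p_value})
        print(f"load-PC vs {label}: rho({res.n - 2 - res.covariates}) = "
              f"{res.rho:+.2f}, p = {res.p_value:.3f}")
    pd.DataFrame(assoc_rows).to_csv(cfg.RESULTS / "behavior_association.csv",
                                    index=False)


if __name__ == "__main__":
    main()
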