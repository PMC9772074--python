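"""Clean every subject: FD censoring, nuisance regression, band-pass.

Reads the simulated sessions from scratch/cohort/, writes cleaned matrices
and retained-frame indices back to scratch, and a censoring summary to
results/censoring.csv.
"""

import importlib
import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
cfg = importlib.import_module("00_config")

from loadmapper import io as lio
from loadmapper.preprocess import build_censor_mask, clean_timeseries, compute_fd_runs


def main() -> None:
    parcel_map = lio.read_parcel_map(cfg.SCRATCH / "parcel_map.tsv")
    subjects = pd.read_csv(cfg.RESULTS / "subjects.csv")
    rows = []
    for sid in subjects["subject"]:
        sdir = cfg.SCRATCH / sid
        motion = [lio.read_motion(sdir / f"motion_run{i}.txt") for i in range(2)]
        boundaries = [0, len(motion[0]), len(motion[0]) + len(motion[1])]
        ts = lio.read_timeseries(sdir / "timeseries.tsv", 2.0, boundaries, parcel_map)
        labels = lio.read_labels(sdir / "labels.tsv")
        fd = compute_fd_runs(motion)
        mask = build_censor_mask(fd, boundaries, threshold=0.2, back=1, forward=2)
        clean = clean_timeseries(ts, motion, mask, labels=labels)
        np.save(sdir / "clean.npy", clean.data)
        np.save(sdir / "retained.npy", clean.retained_indices)
        lio.write_mask(mask, sdir / "censor_mask.txt")
        rows.append({"subject": sid, "n_frames": ts.n_frames,
                     "n_censored": mask.n_censored,
                     "censored_fraction": mask.n_censored / ts.n_frames,
                     "median_fd": float(np.median(fd)), "max_fd": float(fd.max())})
    table = pd.DataFrame(rows)
    table.to_csv(cfg.RESULTS / "censoring.csv", index=False)
    print(f"cleaned {len(table)} subjects; censored fraction "
          f"{table['censored_fraction'].mean():.1%} on average "
          f"(range {table['censored_fraction'].min():.1%}-"
          f"{table['censored_fraction'].max():.1%})")


if __name__ == "__main__":
    main()
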