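#!/usr/bin/env python
"""7-feature PCA of the simulated plates: do the phenotypes segregate?

Assembles the 7-feature vector (MFR, burst rate, burst duration, spike
frequency in bursts, spikes in burst, % spikes in bursts, STTC) for every
well × day of both phenotype plates, standard-score normalizes, projects
onto the first three principal components, and quantifies the separation
of the two groups by the mean silhouette versus a label-permutation null.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from meanet.features import build_feature_matrix, group_separation, pca_project, zscore
from meanet.io import FEATURE_COLUMNS, PipelineConfig, read_spikes
from meanet.pipeline import well_feature_vector

DURATION = 300.0
SIM = Path(__file__).resolve().parents[1] / "results" / "sim"
OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cfg = PipelineConfig()
    vectors, labels = [], []
    for tag, lab in (("hpsc", "hPSC"), ("rat", "rat")):
        for day in range(3):
            table = read_spikes(SIM / f"{tag}_day{day}_spikes.csv", DURATION)
            for well in table.wells():
                v = well_feature_vector(table, well, f"day{day}", cfg)
                if v.complete:
                    vectors.append(v)
                    labels.append(lab)
    matrix, meta = build_feature_matrix(vectors)
    feat_df = pd.concat(
        [meta, pd.DataFrame(matrix, columns=FEATURE_COLUMNS)], axis=1
    )
    feat_df.insert(0, "group", labels)
    feat_df.to_csv(OUT / "features_all.csv", index=False, lineterminator="\n")

    res = pca_project(zscore(matrix), 3)
    scores = meta.copy()
    scores.insert(0, "group", labels)
    for i in range(3):
        scores[f"pc{i + 1}"] = res.scores[:, i]
    scores.to_csv(OUT / "pca_scores.csv", index=False, lineterminator="\n")
    pd.DataFrame(
        {"component": [f"pc{i + 1}" for i in range(res.explained_pct.size)],
         "explained_pct": res.explained_pct}
    ).to_csv(OUT / "pca_explained.csv", index=False, lineterminator="\n")

    sil = group_separation(res.scores, labels, 3)
    rng = np.random.default_rng(1)
    perms = [group_separation(res.scores, rng.permutation(labels), 3) for _ in range(100)]
    p95 = float(np.percentile(perms, 95))
    print(
        f"{matrix.shape[0]} samples; PC1/PC2/PC3 explain "
        f"{res.explained_pct[0]:.1f}/{res.explained_pct[1]:.1f}/"
        f"{res.explained_pct[2]:.1f}% of variance"
    )
    print(f"silhouette of true labels {sil:.3f} vs permutation 95th pct {p95:.3f}")
    with open(OUT / "separation.txt", "w", newline="\n") as fh:
        fh.write(f"silhouette={sil:.4f}\npermutation_p95={p95:.4f}\n")


if __name__ == "__main__":
    main()
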