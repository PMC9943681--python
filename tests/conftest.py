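import numpy as np
import pandas as pd
import pytest

from colocseq.io import CountMatrix, DigestionProfile, GradientDesign

#: the RNase A concentration gradient of the second sequencing experiment
GRID = np.array([0.0, 0.1, 0.2, 0.6, 1.2, 2.0, 2.6, 3.2, 4.0, 6.0])


def profile(f, conc=None, feature="tx", condition="coloc", replicate=None):
    """Build a DigestionProfile from raw arrays with sane defaults."""
    f = np.asarray(f, dtype=float)
    conc = GRID[: len(f)] if conc is None else np.asarray(conc, dtype=float)
    rep = np.array(["r1"] * len(f)) if replicate is None else np.asarray(replicate)
    return DigestionProfile(feature_id=feature, condition=condition,
                            conc=conc, f=f, replicate=rep)


def grid_oracle(A, f, k_max=10.0, n_coarse=(101, 201), n_zoom=3):
    """Independent SS minimiser: exhaustive grid search over (P0, k') with
    local refinement by repeated zooming.  Deliberately ignorant of the
    package's fitting code."""
    p_lo, p_hi, k_lo, k_hi = 0.0, 1.0, 0.0, k_max
    best = None
    for _ in range(n_zoom + 1):
        P = np.linspace(p_lo, p_hi, n_coarse[0])
        K = np.linspace(k_lo, k_hi, n_coarse[1])
        E = np.exp(-np.outer(K, A))                       # (k, A)
        pred = P[:, None, None] + (1 - P)[:, None, None] * E[None, :, :]
        ss = ((pred - f[None, None, :]) ** 2).sum(axis=2)  # (P, K)
        i, j = np.unravel_index(np.argmin(ss), ss.shape)
        best = (float(ss[i, j]), float(P[i]), float(K[j]))
        dp = (p_hi - p_lo) / (n_coarse[0] - 1)
        dk = (k_hi - k_lo) / (n_coarse[1] - 1)
        p_lo, p_hi = max(0.0, P[i] - 2 * dp), min(1.0, P[i] + 2 * dp)
        k_lo, k_hi = max(0.0, K[j] - 2 * dk), K[j] + 2 * dk
    return best  # (ss, P0, k')


@pytest.fixture
def tiny_counts(tmp_path):
    """3-feature x 4-sample experiment on disk (coloc-only, one replicate
    per condition), with hand-checkable normalisation arithmetic."""
    counts = pd.DataFrame(
        {
            "c0": [100, 80, 1000],
            "c2": [50, 80, 1000],
            "m0": [100, 60, 500],
            "m2": [10, 60, 500],
        },
        index=["geneA", "geneB", "spike"],
    )
    sheet = pd.DataFrame({
        "sample_id": ["c0", "c2", "m0", "m2"],
        "condition": ["coloc", "coloc", "mock", "mock"],
        "replicate": ["r1", "r1", "r1", "r1"],
        "rnase_conc_ug_per_ml": [0.0, 2.0, 0.0, 2.0],
    })
    cpath, spath = tmp_path / "counts.tsv", tmp_path / "samples.tsv"
    counts.rename_axis("feature_id").to_csv(cpath, sep="\t")
    sheet.to_csv(spath, sep="\t", index=False)
    return cpath, spath
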