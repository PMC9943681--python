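"""Count-table input, filtering and digestion-profile reconstruction.

A CoLoC-seq experiment sequences intact RNA surviving an RNase A gradient
applied to intact organelles ("coloc") and, in parallel, to a detergent
lysate ("mock").  Every library receives the same amount of an exogenous
spike-in transcript, so read counts can be normalised across libraries and
expressed as the remaining fraction f(A) relative to the untreated (A = 0)
sample of the same replicate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CONDITIONS = ("coloc", "mock")


class ColocError(ValueError):
    """Contract violation in input data or configuration."""


@dataclass
class CountMatrix:
    """Raw read counts, features x samples, plus the spike-in feature id.

    ``counts`` is an integer DataFrame indexed by feature id with one column
    per sample.  The spike-in row must be present and strictly positive in
    every library (it is the normalisation anchor).
    """

    counts: pd.DataFrame
    spikein_id: str
    #: real-valued expected counts from a noise-free simulation; measured
    #: read counts are always integers
    exact: bool = False

    def __post_init__(self) -> None:
        if self.spikein_id not in self.counts.index:
            raise ColocError(f"spike-in feature {self.spikein_id!r} absent from count table")
        if self.counts.index.has_duplicates:
            dup = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise ColocError(f"duplicate feature ids: {dup}")
        vals = self.counts.to_numpy()
        if not self.exact and not np.issubdtype(vals.dtype, np.integer):
            raise ColocError("counts must be integers (reads)")
        if (vals < 0).any():
            raise ColocError("negative counts encountered")
        if (self.counts.loc[self.spikein_id] <= 0).any():
            bad = self.counts.columns[self.counts.loc[self.spikein_id] <= 0].tolist()
            raise ColocError(f"spike-in has zero reads in samples {bad}")

    @property
    def features(self) -> list[str]:
        return self.counts.index.tolist()

    @property
    def samples(self) -> list[str]:
        return self.counts.columns.tolist()


@dataclass
class GradientDesign:
    """Per-sample metadata: condition, replicate, RNase A concentration.

    ``table`` columns: sample_id, condition (coloc|mock), replicate,
    conc_ug_per_ml.  ``digestion_time_s`` is the single shared digestion
    time t (the gradient fixes t and varies the enzyme concentration A).
    """

    table: pd.DataFrame
    digestion_time_s: float = 600.0

    def __post_init__(self) -> None:
        required = {"sample_id", "condition", "replicate", "conc_ug_per_ml"}
        missing = required - set(self.table.columns)
        if missing:
            raise ColocError(f"sample sheet misses columns {sorted(missing)}")
        if self.digestion_time_s <= 0:
            raise ColocError("digestion time must be positive")
        t = self.table
        if t["sample_id"].duplicated().any():
            raise ColocError("duplicate sample ids in sample sheet")
        bad_cond = set(t["condition"]) - set(CONDITIONS)
        if bad_cond:
            raise ColocError(f"unknown conditions {sorted(bad_cond)}; expected {CONDITIONS}")
        if (t["conc_ug_per_ml"] < 0).any():
            raise ColocError("negative RNase concentration")
        for (cond, rep), grp in t.groupby(["condition", "replicate"]):
            conc = grp["conc_ug_per_ml"].to_numpy(dtype=float)
            n_zero = int((conc == 0).sum())
            if n_zero != 1:
                raise ColocError(
                    f"group ({cond}, {rep}) has {n_zero} untreated (A=0) samples; exactly one required"
                )
            if len(np.unique(conc)) != len(conc):
                raise ColocError(f"duplicate RNase concentrations in group ({cond}, {rep})")

    def groups(self):
        """Yield ((condition, replicate), sub-table) pairs, sorted."""
        for key, grp in self.table.groupby(["condition", "replicate"], sort=True):
            yield key, grp.sort_values("conc_ug_per_ml")


@dataclass
class DigestionProfile:
    """Per-transcript, per-condition series of (A, f) measurements.

    Replicates are pooled as points ("compounded"): each replicate
    contributes its own A = 0 anchor with f = 1 by construction.
    """

    feature_id: str
    condition: str
    conc: np.ndarray       # μg/ml
    f: np.ndarray          # remaining fraction, f(0) = 1, may exceed 1
    replicate: np.ndarray  # replicate label per point

    @property
    def n_points(self) -> int:
        return len(self.conc)

    def __post_init__(self) -> None:
        self.conc = np.asarray(self.conc, dtype=float)
        self.f = np.asarray(self.f, dtype=float)
        self.replicate = np.asarray(self.replicate)
        if not (len(self.conc) == len(self.f) == len(self.replicate)):
            raise ColocError("profile arrays must have equal length")
        if not np.isfinite(self.f).all() or (self.f < 0).any():
            raise ColocError(f"{self.feature_id}/{self.condition}: f must be finite and >= 0")


def load_counts(count_table_path, sample_sheet_path, spikein_id: str,
                digestion_time_s: float = 600.0) -> tuple[CountMatrix, GradientDesign]:
    """Read a TSV count table and sample sheet into validated containers.

    The count table has a header row of sample ids and the feature id in the
    first column; cells are integer read counts.  The sample sheet carries
    sample_id, condition, replicate and rnase_conc_ug_per_ml columns.
    """
    raw = pd.read_csv(count_table_path, sep="\t", index_col=0)
    # reject fractional reads before any dtype coercion
    as_float = raw.astype(float)
    if not np.allclose(as_float.to_numpy() % 1, 0):
        raise ColocError("non-integer read counts in count table")
    counts = as_float.astype(np.int64)
    counts.index = counts.index.astype(str)

    sheet = pd.read_csv(sample_sheet_path, sep="\t", dtype={"sample_id": str, "replicate": str})
    sheet = sheet.rename(columns={"rnase_conc_ug_per_ml": "conc_ug_per_ml"})
    design = GradientDesign(sheet, digestion_time_s=digestion_time_s)

    missing = set(counts.columns) - set(sheet["sample_id"])
    if missing:
        raise ColocError(f"samples in count table absent from sheet: {sorted(missing)}")
    extra = set(sheet["sample_id"]) - set(counts.columns)
    if extra:
        raise ColocError(f"samples in sheet absent from count table: {sorted(extra)}")
    # harmonize orders
    counts = counts[sheet["sample_id"].tolist()]
    return CountMatrix(counts, spikein_id), design


def compound_features(cm: CountMatrix, groups: dict[str, list[str]]) -> CountMatrix:
    """Sum repeated gene copies into single compound entries.

    Repetitive genes (multicopy tRNAs, rRNA repeats ...) attract reads that
    cannot be attributed to one copy; their rows are summed under one id.
    """
    if not groups:
        return cm
    all_members: list[str] = []
    for cid, members in groups.items():
        for m in members:
            if m not in cm.counts.index:
                raise ColocError(f"compound group {cid!r}: member {m!r} not in count table")
        all_members.extend(members)
    if len(set(all_members)) != len(all_members):
        raise ColocError("compound groups overlap")
    if cm.spikein_id in all_members:
        raise ColocError("spike-in cannot be compounded")

    counts = cm.counts.drop(index=all_members)
    new_rows = {cid: cm.counts.loc[members].sum(axis=0) for cid, members in groups.items()}
    out = pd.concat([counts, pd.DataFrame(new_rows).T.astype(np.int64)])
    return CountMatrix(out, cm.spikein_id)


def exclude_features(cm: CountMatrix, blacklist: list[str]) -> CountMatrix:
    """Drop cross-mapping features (user-supplied blacklist).

    The spike-in is never removable.  Unknown ids are ignored with a warning
    (blacklists are often shared across annotation versions).
    """
    if cm.spikein_id in blacklist:
        raise ColocError("blacklist must not contain the spike-in feature")
    present = [b for b in blacklist if b in cm.counts.index]
    unknown = sorted(set(blacklist) - set(present))
    if unknown:
        logger.warning("blacklist ids not in count table (ignored): %s", unknown)
    if not present:
        return cm
    return CountMatrix(cm.counts.drop(index=present), cm.spikein_id)


def filter_min_untreated(cm: CountMatrix, design: GradientDesign, cutoff: int = 30) -> CountMatrix:
    """Keep features with >= ``cutoff`` raw reads in every untreated library.

    The untreated (A = 0) sample sets the reference level f = 1; a noisy
    starting level corrupts the whole profile, so the threshold is applied
    to every A = 0 sample of both conditions (boundary inclusive).
    """
    if cutoff < 0:
        raise ColocError("cutoff must be >= 0")
    zero_samples = design.table.loc[design.table["conc_ug_per_ml"] == 0, "sample_id"].tolist()
    keep = (cm.counts[zero_samples] >= cutoff).all(axis=1)
    keep.loc[cm.spikein_id] = True
    logger.info("untreated-count filter (>= %d): %d of %d features retained",
                cutoff, int(keep.sum()), len(keep))
    return CountMatrix(cm.counts.loc[keep], cm.spikein_id)


def build_profiles(cm: CountMatrix, design: GradientDesign) -> list[DigestionProfile]:
    """Spike-in-normalise counts and reconstruct per-transcript digestion profiles.

    For feature i in library s of replicate group g with untreated library s0:

        f = (count[i, s] / count[spike, s]) / (count[i, s0] / count[spike, s0])

    so f(0) = 1 by construction and any library-size factor cancels through
    the spike-in.  Replicates of a condition are pooled as points into a
    single profile per (feature, condition).  Features with zero reads in an
    untreated library cannot be anchored and are skipped with a warning.
    """
    spike = cm.counts.loc[cm.spikein_id].astype(float)
    if (spike <= 0).any():
        raise ColocError("spike-in count must be positive in every sample")

    features = [fid for fid in cm.counts.index if fid != cm.spikein_id]
    norm = cm.counts.loc[features].astype(float).div(spike, axis=1)

    # accumulate points per (feature, condition)
    pts: dict[tuple[str, str], list[tuple[float, float, str]]] = {}
    skipped: set[str] = set()
    for (cond, rep), grp in design.groups():
        s0 = grp.loc[grp["conc_ug_per_ml"] == 0, "sample_id"].iloc[0]
        ref = norm[s0]
        for fid in features:
            if ref[fid] == 0:
                skipped.add(fid)
                continue
            for _, row in grp.iterrows():
                f = norm.at[fid, row["sample_id"]] / ref[fid]
                pts.setdefault((fid, cond), []).append((row["conc_ug_per_ml"], f, rep))
    if skipped:
        logger.warning("features with zero reads in an untreated sample, "
                       "excluded from profiling: %s", sorted(skipped))

    profiles = []
    for fid in features:
        for cond in CONDITIONS:
            if fid in skipped or (fid, cond) not in pts:
                continue
            arr = pts[(fid, cond)]
            profiles.append(DigestionProfile(
                feature_id=fid, condition=cond,
                conc=np.array([p[0] for p in arr]),
                f=np.array([p[1] for p in arr]),
                replicate=np.array([p[2] for p in arr]),
            ))
    return profiles


def profiles_to_frame(profiles: list[DigestionProfile]) -> pd.DataFrame:
    """Long-format table of profile points (feature, condition, replicate, A, f)."""
    rows = []
    for p in profiles:
        for a, f, rep in zip(p.conc, p.f, p.replicate):
            rows.append((p.feature_id, p.condition, rep, a, f))
    return pd.DataFrame(rows, columns=["feature_id", "condition", "replicate",
                                       "conc_ug_per_ml", "f"])


def write_profiles(profiles: list[DigestionProfile], path) -> None:
    profiles_to_frame(profiles).to_csv(path, sep="\t", index=False)
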