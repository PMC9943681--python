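"""Pipeline orchestration: configuration, fitting, classification, reporting.

Library-level counterparts of the command-line subcommands.  Every output
directory receives a verbatim copy of the effective configuration plus a
run manifest, so each result table can be traced to the exact thresholds
that produced it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import classify as _classify
from . import io as _io
from . import kinetics as _kin

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunables of the analysis, serialised into every output directory."""

    counts: str = ""
    samples: str = ""
    blacklist: str = ""
    compounds: str = ""
    outdir: str = "."
    spikein_id: str = "spikein"
    cutoff: int = 30
    tau_low: float = 0.1
    tau_high: float = 0.2
    require_ci: bool = True
    ci_level: float = 0.95
    dependency_threshold: float = 0.3
    max_iter: int = 500
    tolerance: float = 1e-9
    digestion_time_s: float = 600.0
    enzyme_mw: float = 13700.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("tau_low", "tau_high", "ci_level", "dependency_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise _io.ColocError(f"{name} must lie in [0, 1], got {v}")
        if self.cutoff < 0:
            raise _io.ColocError("cutoff must be >= 0")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    def write(self, outdir) -> Path:
        """Flat key:value provenance file."""
        path = Path(outdir) / "config.txt"
        with open(path, "w") as fh:
            for key, value in asdict(self).items():
                fh.write(f"{key}: {value}\n")
            fh.write(f"config_hash: {self.config_hash()}\n")
        return path

    @classmethod
    def read(cls, path) -> "PipelineConfig":
        fields = {f.name: f.type for f in cls.__dataclass_fields__.values()}
        kwargs = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#") or ":" not in line:
                continue
            key, _, value = line.partition(":")
            key, value = key.strip(), value.strip()
            if key == "config_hash" or key not in cls.__dataclass_fields__:
                continue
            current = getattr(cls(), key)
            if isinstance(current, bool):
                kwargs[key] = value.lower() in ("1", "true", "yes")
            elif isinstance(current, int):
                kwargs[key] = int(value)
            elif isinstance(current, float):
                kwargs[key] = float(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)


def _read_blacklist(path) -> list[str]:
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]


def _read_compounds(path) -> dict[str, list[str]]:
    """Two-column TSV: compound_id <tab> member_id."""
    groups: dict[str, list[str]] = {}
    for ln in Path(path).read_text().splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        cid, member = ln.split("\t")[:2]
        groups.setdefault(cid, []).append(member)
    return groups


def _manifest(cfg: PipelineConfig, outdir: Path, stage: str, extra: dict) -> None:
    manifest = {"stage": stage, "config_hash": cfg.config_hash(), **extra}
    with open(outdir / f"manifest_{stage}.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def fits_to_frame(fits: list[_kin.KineticsFit], enzyme_mw: float, t: float) -> pd.DataFrame:
    rows = []
    for f in fits:
        rows.append({
            "feature_id": f.feature_id, "condition": f.condition, "model": f.model,
            "P0": f.P0, "P0_lo": f.P0_ci[0], "P0_hi": f.P0_ci[1],
            "k_prime": f.k_prime, "k_lo": f.k_ci[0], "k_hi": f.k_ci[1],
            "k_M_per_s": _kin.convert_rate(f.k_prime, enzyme_mw, t).k,
            "r_squared": f.r_squared, "dependency": f.dependency,
            "converged": f.converged, "n_points": f.n_points,
            "mean_f": f.mean_f,
        })
    return pd.DataFrame(rows)


def run_fit(cfg: PipelineConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Load counts, filter, normalise, fit every retained profile.

    Writes profiles.tsv and fits.tsv into cfg.outdir and returns the two
    tables.  Logging reports feature counts at each filtering stage.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cm, design = _io.load_counts(cfg.counts, cfg.samples, cfg.spikein_id,
                                 digestion_time_s=cfg.digestion_time_s)
    logger.info("loaded %d features x %d samples", len(cm.features), len(cm.samples))
    if cfg.compounds:
        cm = _io.compound_features(cm, _read_compounds(cfg.compounds))
        logger.info("after compounding: %d features", len(cm.features))
    if cfg.blacklist:
        cm = _io.exclude_features(cm, _read_blacklist(cfg.blacklist))
        logger.info("after blacklist: %d features", len(cm.features))
    cm = _io.filter_min_untreated(cm, design, cfg.cutoff)
    logger.info("after untreated cutoff >= %d: %d features", cfg.cutoff, len(cm.features))

    profiles = _io.build_profiles(cm, design)
    logger.info("built %d profiles", len(profiles))
    fits = []
    for prof in profiles:
        fit = _kin.select_model(prof, dependency_threshold=cfg.dependency_threshold,
                                max_iter=cfg.max_iter, tol=cfg.tolerance)
        fit = _kin.confidence_intervals(fit, prof, level=cfg.ci_level,
                                        max_iter=cfg.max_iter, tol=cfg.tolerance)
        fits.append(fit)

    prof_df = _io.profiles_to_frame(profiles)
    fit_df = fits_to_frame(fits, cfg.enzyme_mw, cfg.digestion_time_s)
    prof_df.to_csv(outdir / "profiles.tsv", sep="\t", index=False)
    fit_df.to_csv(outdir / "fits.tsv", sep="\t", index=False)
    cfg.write(outdir)
    _manifest(cfg, outdir, "fit", {"n_features": len(cm.features) - 1,
                                   "n_profiles": len(profiles)})
    return prof_df, fit_df


def run_classify(fit_df: pd.DataFrame, cfg: PipelineConfig,
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pair coloc/mock fits per feature and call localisation topology.

    Features lacking one of the two conditions are reported in
    unpaired.tsv rather than silently dropped.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    fits: dict[tuple[str, str], _kin.KineticsFit] = {}
    for _, row in fit_df.iterrows():
        fits[(row["feature_id"], row["condition"])] = _kin.KineticsFit(
            feature_id=row["feature_id"], condition=row["condition"],
            model=row["model"], P0=row["P0"], k_prime=row["k_prime"],
            r_squared=row["r_squared"], dependency=row["dependency"],
            converged=bool(row["converged"]), n_points=int(row["n_points"]),
            residual_ss=0.0, P0_ci=(row["P0_lo"], row["P0_hi"]),
            k_ci=(row["k_lo"], row["k_hi"]), mean_f=row.get("mean_f", float("nan")),
        )
    features = sorted({fid for fid, _ in fits})
    calls, unpaired = [], []
    for fid in features:
        coloc, mock = fits.get((fid, "coloc")), fits.get((fid, "mock"))
        if coloc is None or mock is None:
            unpaired.append(fid)
            continue
        calls.append(_classify.classify_transcript(
            coloc, mock, tau_low=cfg.tau_low, tau_high=cfg.tau_high,
            require_ci=cfg.require_ci))

    call_df = _classify.calls_to_frame(calls)
    summary = _classify.summarize_landscape(calls)
    summary.insert(0, "tau_high", cfg.tau_high)
    summary.insert(0, "tau_low", cfg.tau_low)
    call_df.to_csv(outdir / "calls.tsv", sep="\t", index=False)
    summary.to_csv(outdir / "landscape.tsv", sep="\t", index=False)
    pd.DataFrame({"feature_id": unpaired}).to_csv(outdir / "unpaired.tsv",
                                                  sep="\t", index=False)
    cfg.write(outdir)
    _manifest(cfg, outdir, "classify", {"n_calls": len(calls),
                                        "n_unpaired": len(unpaired)})
    return call_df, summary


def composition_report(cm: _io.CountMatrix, design: _io.GradientDesign,
                       class_map: dict[str, str]) -> pd.DataFrame:
    """Per-library read fractions by feature class, ordered by A within condition.

    With intact membranes, protected classes take an increasing share of the
    library as the gradient digests everything else; after lysis the shares
    stay roughly flat.  Unmapped features fall into an "other" class.
    """
    features = [f for f in cm.features if f != cm.spikein_id]
    unmapped = [f for f in features if f not in class_map]
    if unmapped:
        logger.warning("%d features without class assignment -> 'other'", len(unmapped))
    classes = sorted({class_map.get(f, "other") for f in features})
    counts = cm.counts.loc[features]
    grouping = pd.Series({f: class_map.get(f, "other") for f in features})
    by_class = counts.groupby(grouping).sum()
    fractions = by_class.div(by_class.sum(axis=0), axis=1)

    rows = []
    tbl = design.table.sort_values(["condition", "replicate", "conc_ug_per_ml"])
    for _, s in tbl.iterrows():
        row = {"sample_id": s["sample_id"], "condition": s["condition"],
               "replicate": s["replicate"], "conc_ug_per_ml": s["conc_ug_per_ml"]}
        for cls in classes:
            row[cls] = float(fractions.at[cls, s["sample_id"]]) if cls in fractions.index else 0.0
        rows.append(row)
    return pd.DataFrame(rows)
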