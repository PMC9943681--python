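"""Localisation-topology calls from paired intact/lysed-organelle fits.

Comparing the protected fraction P0 estimated with intact membranes (coloc)
against the lysed control (mock) separates three behaviours:

* degradable contaminant — decays in both setups (low P0 twice);
* resident — protected only while membranes are intact (high coloc P0,
  low mock P0);
* RNase-resistant — plateaus in both setups, i.e. protection independent of
  membranes (tight structure / dense RNP shielding), a potential false
  positive that only orthogonal methods can resolve.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io import ColocError
from .kinetics import MODEL2, KineticsFit

CATEGORIES = ("resident", "degradable_contaminant", "rnase_resistant", "ambiguous")

#: flat-profile heuristics: a coloc profile is "flat" when its mean remaining
#: fraction exceeds this level with an essentially null digestion rate
FLAT_MEAN_F = 0.8
FLAT_K_PRIME = 0.05


@dataclass
class TopologyCall:
    feature_id: str
    category: str
    coloc_P0: float
    mock_P0: float
    coloc_P0_lo: float
    evidence: str


def classify_transcript(coloc: KineticsFit, mock: KineticsFit,
                        tau_low: float = 0.1, tau_high: float = 0.2,
                        require_ci: bool = True) -> TopologyCall:
    """Quadrant classification of one transcript from its paired fits.

    Rules, in order:

    1. flat-coloc rule: a coloc profile so flat that P0 was unidentifiable
       (Model-2 fallback with mean f > 0.8 and k' ~ 0) paired with a cleanly
       decaying mock profile is called resident — nothing degraded while
       membranes were intact, so the plateau is real even though the fit
       could not place it.
    2. degradable_contaminant: P0 < tau_low in both conditions.
    3. resident: coloc P0 >= tau_high and mock P0 < tau_low; with
       ``require_ci`` the coloc P0 lower confidence bound must also clear
       tau_low (a *significant* protected pool).
    4. rnase_resistant: coloc P0 >= tau_high and mock P0 >= tau_low.
    5. otherwise ambiguous.

    Model-2 fits carry P0 = 0 by construction.
    """
    if coloc.feature_id != mock.feature_id:
        raise ColocError(
            f"paired fits refer to different features: {coloc.feature_id!r} vs {mock.feature_id!r}")
    for name, thr in (("tau_low", tau_low), ("tau_high", tau_high)):
        if not 0.0 <= thr <= 1.0:
            raise ColocError(f"{name} must lie in [0, 1]")

    cp, mp = coloc.P0, mock.P0
    lo = coloc.P0_ci[0]

    if (coloc.model == MODEL2 and coloc.mean_f > FLAT_MEAN_F
            and coloc.k_prime < FLAT_K_PRIME and mp < tau_low and mock.converged):
        cat, rule = "resident", "flat-coloc rule"
    elif cp < tau_low and mp < tau_low:
        cat, rule = "degradable_contaminant", f"coloc P0 and mock P0 < {tau_low}"
    elif cp >= tau_high and mp < tau_low:
        if require_ci and not lo > tau_low:
            cat, rule = "ambiguous", f"coloc P0 >= {tau_high} but lower CI <= {tau_low}"
        else:
            cat, rule = "resident", f"coloc P0 >= {tau_high}, mock P0 < {tau_low}"
    elif cp >= tau_high and mp >= tau_low:
        cat, rule = "rnase_resistant", f"coloc P0 >= {tau_high}, mock P0 >= {tau_low}"
    else:
        cat, rule = "ambiguous", "between thresholds"

    return TopologyCall(feature_id=coloc.feature_id, category=cat,
                        coloc_P0=cp, mock_P0=mp, coloc_P0_lo=lo, evidence=rule)


def summarize_landscape(calls: list[TopologyCall]) -> pd.DataFrame:
    """Counts, fractions and member lists per topology category.

    Deterministic ordering (fixed category order, sorted feature lists);
    duplicate feature ids violate the one-call-per-transcript contract.
    """
    ids = [c.feature_id for c in calls]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ColocError(f"duplicate feature ids in calls: {dup}")
    total = len(calls)
    rows = []
    for cat in CATEGORIES:
        members = sorted(c.feature_id for c in calls if c.category == cat)
        rows.append({
            "category": cat,
            "n": len(members),
            "fraction": len(members) / total if total else 0.0,
            "features": ",".join(members),
        })
    return pd.DataFrame(rows)


def calls_to_frame(calls: list[TopologyCall]) -> pd.DataFrame:
    return pd.DataFrame([{
        "feature_id": c.feature_id, "category": c.category,
        "coloc_P0": c.coloc_P0, "coloc_P0_lo": c.coloc_P0_lo,
        "mock_P0": c.mock_P0, "rule": c.evidence,
    } for c in calls])
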