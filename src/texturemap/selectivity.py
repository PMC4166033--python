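"""Selectivity index and texture-preference classification.

A neuron's selectivity index is SI = (max - min) / max over its
per-condition response peaks (and, independently, areas).  Responsive
neurons with SI at or above threshold AND a significant omnibus
difference across conditions (ANOVA when Levene's test accepts equal
variances, Kruskal-Wallis otherwise) are classed "preferring"; other
responsive neurons are "non-preferring"; the rest "non-responsive".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

SI_THRESHOLD = 0.35

CLASS_PREFERRING = "preferring"
CLASS_NON_PREFERRING = "non-preferring"
CLASS_NON_RESPONSIVE = "non-responsive"


def selectivity_index(peaks: Sequence[float]) -> float:
    """SI = (max - min) / max of the per-condition peaks.

    0 for a flat tuning curve, 1 when the weakest condition evokes
    nothing.  Undefined (ValueError) when the maximum is not positive —
    such a neuron is routed to the non-responsive class upstream.
    """
    p = np.asarray(peaks, dtype=float)
    if p.size < 2:
        raise ValueError("need at least two conditions")
    if np.any(p < 0):
        p = np.clip(p, 0.0, None)  # negative peaks carry no response
    mx = p.max()
    if mx <= 0:
        raise ValueError("SI undefined for non-positive maximum peak")
    return float((mx - p.min()) / mx)


@dataclass
class SelectivityResult:
    neuron_id: int
    si_peak: float
    si_area: float
    preferred: str | None
    preferred_by_area: str | None
    p_omnibus: float
    omnibus_test: str
    cls: str
    concordant: bool


def _omnibus(groups: list[np.ndarray], levene_alpha: float = 0.05) -> tuple[float, str]:
    """ANOVA across condition groups when Levene's test accepts equal
    variances at ``levene_alpha``, Kruskal-Wallis otherwise."""
    groups = [np.asarray(g, dtype=float) for g in groups if len(g) > 1]
    if len(groups) < 2:
        return np.nan, "none"
    if all(np.ptp(g) == 0 for g in groups):
        return 1.0, "anova"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, p_lev = stats.levene(*groups)
        if np.isnan(p_lev) or p_lev >= levene_alpha:
            _, p = stats.f_oneway(*groups)
            return float(p), "anova"
        _, p = stats.kruskal(*groups)
        return float(p), "kruskal"


def classify(
    neuron_id: int,
    peaks: Mapping[str, float],
    areas: Mapping[str, float],
    trial_values: Mapping[str, np.ndarray],
    responsive: bool,
    si_threshold: float = SI_THRESHOLD,
    alpha: float = 0.01,
    levene_alpha: float = 0.05,
    conditions: Sequence[str] | None = None,
) -> SelectivityResult:
    """Classify one neuron from its per-condition response summaries.

    ``trial_values`` are the per-trial peaks per condition used by the
    omnibus test.  ``conditions`` restricts which labels enter the SI /
    classification (defaults to all keys of ``peaks``).
    """
    conds = list(conditions) if conditions is not None else list(peaks)
    if len(conds) < 2:
        raise ValueError("classification needs >= 2 conditions")
    pk = np.array([peaks[c] for c in conds], dtype=float)
    ar = np.array([areas[c] for c in conds], dtype=float)
    if not responsive or pk.max() <= 0:
        return SelectivityResult(
            neuron_id, np.nan, np.nan, None, None, np.nan, "none",
            CLASS_NON_RESPONSIVE, True,
        )
    si_peak = selectivity_index(pk)
    si_area = selectivity_index(ar) if ar.max() > 0 else np.nan
    preferred = conds[int(np.argmax(pk))]
    preferred_by_area = conds[int(np.argmax(ar))] if ar.max() > 0 else None
    p_omni, test = _omnibus(
        [np.asarray(trial_values[c]) for c in conds], levene_alpha=levene_alpha
    )
    cls = (
        CLASS_PREFERRING
        if si_peak >= si_threshold and p_omni < alpha
        else CLASS_NON_PREFERRING
    )
    concordant = preferred_by_area == preferred
    return SelectivityResult(
        neuron_id, si_peak, si_area, preferred, preferred_by_area,
        p_omni, test, cls, concordant,
    )


def concordance(results: Sequence[SelectivityResult]) -> float:
    """Fraction of preferring neurons whose peak- and area-based preferred
    conditions agree (NaN when no neuron prefers)."""
    pref = [r for r in results if r.cls == CLASS_PREFERRING]
    if not pref:
        return np.nan
    return float(np.mean([r.concordant for r in pref]))


def classify_population(
    summaries: pd.DataFrame,
    trial_peaks: pd.DataFrame,
    si_threshold: float = SI_THRESHOLD,
    alpha: float = 0.01,
    levene_alpha: float = 0.05,
    conditions: Sequence[str] | None = None,
    omnibus_on: Literal["trial_peak", "trial_area"] = "trial_peak",
) -> pd.DataFrame:
    """Classify every neuron of an experiment.

    ``summaries`` / ``trial_peaks`` come from
    :func:`texturemap.trace_processing.summarize_trial_set`.  A neuron
    counts as responsive when any condition passed the responsiveness test
    and its decay-filter flag held.  Returns one row per neuron.
    """
    rows = []
    results = []
    for nid, g in summaries.groupby("neuron_id"):
        peaks = dict(zip(g["condition"], g["peak"]))
        areas = dict(zip(g["condition"], g["area"]))
        # decay exclusion is per neuron, judged on the strongest response
        # (weak conditions give unreliable tau fits)
        tau_ok = bool(g.loc[g["peak"].idxmax(), "tau_kept"]) if len(g) else True
        responsive = bool(g["responsive"].any() and tau_ok and g["stable"].all())
        tp = trial_peaks[trial_peaks["neuron_id"] == nid]
        tvals = {c: sub[omnibus_on].to_numpy() for c, sub in tp.groupby("condition")}
        res = classify(
            int(nid), peaks, areas, tvals, responsive,
            si_threshold=si_threshold, alpha=alpha, levene_alpha=levene_alpha,
            conditions=conditions,
        )
        results.append(res)
        rows.append(
            {
                "neuron_id": res.neuron_id,
                "class": res.cls,
                "preferred": res.preferred,
                "preferred_by_area": res.preferred_by_area,
                "SI_peak": res.si_peak,
                "SI_area": res.si_area,
                "p_omnibus": res.p_omnibus,
                "omnibus_test": res.omnibus_test,
                "concordant": res.concordant,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["concordance"] = concordance(results)
    return df
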