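"""Five-category smoking composition from nested binary-model posteriors.

Separate smoothing models are fitted to a nested ladder of binary
indicators — heavy, heavy+moderate, current (heavy+moderate+light) and
ever (current+former) — and the full composition {heavy, moderate, light,
former, never} is recovered per posterior draw by successive differencing
down the ladder.  Negative differences, which can occur because the
ladder fits are separate models, are clamped to zero and each draw's
5-vector is rescaled to sum to one ("clamp and rescale").  Draws are
paired across fits by draw index, a conservative coupling that preserves
each fit's marginal uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CATEGORIES = ("heavy", "moderate", "light", "former", "never")

#: the nested ladder, inner to outer; each fit's indicator is a superset of
#: the previous one
LADDER = ("heavy", "heavy_moderate", "current", "ever")


@dataclass(frozen=True)
class CategoryComposition:
    """Per-area posterior draws of the 5-category composition.

    ``draws`` maps category name to an (n_draws, n_areas) array; every
    draw's 5-vector is non-negative and sums to exactly 1 after rescaling.
    """

    area_ids: tuple
    draws: dict

    @property
    def n_draws(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    def stack(self) -> np.ndarray:
        """(n_draws, n_areas, 5) array in canonical category order."""
        return np.stack([self.draws[c] for c in CATEGORIES], axis=-1)


def decompose_pair(p_outer_draws: np.ndarray, p_inner_draws: np.ndarray) -> np.ndarray:
    """Paired difference of a broader and a nested indicator, clamped at 0.

    E.g. former = ever - current.  Arrays must be aligned draw-by-draw and
    area-by-area.
    """
    outer = np.asarray(p_outer_draws, dtype=float)
    inner = np.asarray(p_inner_draws, dtype=float)
    if outer.shape != inner.shape:
        raise ValueError(f"misaligned draw arrays: {outer.shape} vs {inner.shape}")
    return np.maximum(outer - inner, 0.0)


def assemble_composition(fits: dict, area_ids=None) -> CategoryComposition:
    """Combine ladder-fit draws into a simplex-valued 5-category composition.

    ``fits`` maps each :data:`LADDER` name to an (n_draws, n_areas) array of
    prevalence draws (aligned across fits).  Differencing gives
    moderate = heavy_moderate - heavy, light = current - heavy_moderate,
    former = ever - current, never = 1 - ever, each clamped at zero; the
    resulting 5-vector is rescaled to sum to one wherever clamping (or a
    ladder inversion) moved the total away from one.
    """
    missing = [k for k in LADDER if k not in fits]
    if missing:
        raise ValueError(f"missing ladder fits: {missing}")
    arrs = {k: np.asarray(fits[k], dtype=float) for k in LADDER}
    shapes = {a.shape for a in arrs.values()}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent draw shapes across fits: {shapes}")

    heavy = np.maximum(arrs["heavy"], 0.0)
    moderate = decompose_pair(arrs["heavy_moderate"], arrs["heavy"])
    light = decompose_pair(arrs["current"], arrs["heavy_moderate"])
    former = decompose_pair(arrs["ever"], arrs["current"])
    never = decompose_pair(np.ones_like(arrs["ever"]), arrs["ever"])

    total = heavy + moderate + light + former + never
    draws = {
        "heavy": heavy / total,
        "moderate": moderate / total,
        "light": light / total,
        "former": former / total,
        "never": never / total,
    }
    n_areas = next(iter(shapes))[1]
    ids = tuple(area_ids) if area_ids is not None else tuple(range(n_areas))
    if len(ids) != n_areas:
        raise ValueError("area_ids length does not match draw arrays")
    return CategoryComposition(area_ids=ids, draws=draws)


def estimate_stratum_ratios(microdata: pd.DataFrame, weight_col: str = "ps_weight") -> pd.DataFrame:
    """Weighted stratum-vs-national prevalence ratios per category.

    For each age-gender stratum s and category c the ratio is the weighted
    prevalence of c within s divided by the national weighted prevalence
    of c, from non-missing respondents.  Used to disaggregate an
    area-level composition fit into stratum-level compositions for the
    stratified attributable-mortality scenario; assumes the age-gender
    tilt of smoking is shared across areas (it is, in the generator).
    """
    rows = microdata[microdata["smoking"].notna()].copy()
    if rows.empty:
        raise ValueError("no non-missing respondents")
    rows["stratum"] = rows["age_group"] + "_" + rows["gender"]
    w = rows[weight_col]
    national = {
        c: float(w[rows["smoking"] == c].sum() / w.sum()) for c in CATEGORIES
    }
    out = {}
    for s, grp in rows.groupby("stratum"):
        ws = grp[weight_col]
        out[s] = [
            (float(ws[grp["smoking"] == c].sum() / ws.sum()) / national[c])
            if national[c] > 0
            else 1.0
            for c in CATEGORIES
        ]
    return pd.DataFrame.from_dict(out, orient="index", columns=list(CATEGORIES))


def stratify_composition(comp: CategoryComposition, ratios: pd.DataFrame) -> dict:
    """Disaggregate area-level composition draws into stratum compositions.

    Each stratum's draws are the area draws tilted by the stratum's
    category ratios and renormalized to the simplex, preserving the
    draw pairing across strata.
    """
    out = {}
    for s in ratios.index:
        r = ratios.loc[s, list(CATEGORIES)].to_numpy(dtype=float)
        tilted = {c: comp.draws[c] * r[j] for j, c in enumerate(CATEGORIES)}
        total = sum(tilted.values())
        out[s] = CategoryComposition(
            area_ids=comp.area_ids,
            draws={c: tilted[c] / total for c in CATEGORIES},
        )
    return out


def composition_summaries(comp: CategoryComposition) -> pd.DataFrame:
    """Per-area, per-category posterior mean and equal-tailed 95% interval."""
    if comp.n_draws < 100:
        raise ValueError("need at least 100 draws for stable interval summaries")
    rows = []
    for cat in CATEGORIES:
        d = comp.draws[cat]
        rows.append(
            pd.DataFrame(
                {
                    "area": comp.area_ids,
                    "category": cat,
                    "mean": d.mean(axis=0),
                    "q2.5": np.quantile(d, 0.025, axis=0),
                    "q97.5": np.quantile(d, 0.975, axis=0),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
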