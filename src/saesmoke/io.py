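"""Readers and writers for the pipeline's delimited-text formats.

All tables are comma-separated UTF-8 with dot decimals and a documented
header; adjacency uses a GAL-style neighbor list (one line per area: the
area id followed by its neighbors' ids, whitespace-separated).  Every
writer is the lossless round-trip partner of its reader.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .decompose import CATEGORIES, CategoryComposition
from .graph import AdjacencyGraph
from .simulate import EDU_LEVELS, STRATA, AreaPopulation, MortalityTable, TruePrevalence

MICRODATA_COLUMNS = [
    "area", "cluster", "age_group", "gender", "education",
    "incl_prob", "design_weight", "ps_weight", "smoking",
]


def write_microdata(md: pd.DataFrame, path) -> None:
    md.to_csv(path, index=False, columns=MICRODATA_COLUMNS, na_rep="")


def read_microdata(path) -> pd.DataFrame:
    """Read respondent microdata, validating weights and category labels.

    Malformed rows are reported with their 1-based data line number.
    Empty smoking fields become missing values.
    """
    md = pd.read_csv(
        path,
        dtype={"area": str, "cluster": str, "age_group": str, "gender": str,
               "education": str, "smoking": "string"},
        float_precision="round_trip",
    )
    missing_cols = set(MICRODATA_COLUMNS) - set(md.columns)
    if missing_cols:
        raise ValueError(f"microdata header lacks columns {sorted(missing_cols)}")
    for col in ("incl_prob", "design_weight", "ps_weight"):
        bad = ~(md[col] > 0)
        if bad.any():
            line = int(np.flatnonzero(bad)[0]) + 1
            raise ValueError(f"non-positive {col} at data line {line}")
    bad_pi = md["incl_prob"] > 1
    if bad_pi.any():
        line = int(np.flatnonzero(bad_pi)[0]) + 1
        raise ValueError(f"inclusion probability > 1 at data line {line}")
    known = set(CATEGORIES)
    smoking = md["smoking"]
    bad_cat = smoking.notna() & ~smoking.isin(known)
    if bad_cat.any():
        line = int(np.flatnonzero(bad_cat)[0]) + 1
        raise ValueError(
            f"unknown smoking category {smoking[bad_cat].iloc[0]!r} at data line {line}"
        )
    bad_edu = ~md["education"].isin(EDU_LEVELS)
    if bad_edu.any():
        line = int(np.flatnonzero(bad_edu)[0]) + 1
        raise ValueError(f"unknown education level at data line {line}")
    return md


def write_adjacency(graph: AdjacencyGraph, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for a in graph.area_ids:
            nbs = " ".join(str(b) for b in sorted(graph.neighbors[a]))
            fh.write(f"{a} {nbs}".rstrip() + "\n")


def read_adjacency(path) -> AdjacencyGraph:
    """Read a GAL-style neighbor list; asymmetry or self-loops are errors.

    The file must already be symmetric — a one-sided edge is reported with
    the offending pair, never silently repaired.
    """
    neighbors = {}
    order = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            a, nbs = parts[0], parts[1:]
            if a in neighbors:
                raise ValueError(f"area {a!r} listed twice")
            order.append(a)
            neighbors[a] = frozenset(nbs)
    return AdjacencyGraph(tuple(order), neighbors)


_POP_COLS = (
    ["pop15plus"]
    + [f"age_{a}" for a in ("15-39", "40-64", "65+")]
    + ["male_share", "female_share"]
    + [f"edu_{e}" for e in EDU_LEVELS]
    + [f"n_{s}" for s in STRATA]
)


def write_population(pop: AreaPopulation, path) -> None:
    pop.table.to_csv(path, index=True, index_label="area")


def read_population(path) -> AreaPopulation:
    t = pd.read_csv(path, dtype={"area": str}, float_precision="round_trip").set_index("area")
    missing = set(_POP_COLS) - set(t.columns)
    if missing:
        raise ValueError(f"population table lacks columns {sorted(missing)}")
    return AreaPopulation(t[_POP_COLS])


def write_mortality(mt: MortalityTable, path) -> None:
    mt.table.to_csv(path, index=True)


def read_mortality(path) -> MortalityTable:
    t = pd.read_csv(path, dtype={"area": str, "stratum": str}, float_precision="round_trip").set_index(["area", "stratum"])
    if (t["deaths"] < 0).any():
        raise ValueError("negative death counts")
    for col, default in (("expected_deaths", np.nan), ("true_paf", np.nan), ("true_sam", np.nan)):
        if col not in t.columns:
            t[col] = default
    return MortalityTable(t)


def write_truth(truth: TruePrevalence, area_path, stratum_path) -> None:
    area = truth.area.copy()
    area["b"] = truth.b
    area["eta"] = truth.eta
    area.to_csv(area_path, index=True, index_label="area")
    truth.stratum.to_csv(stratum_path, index=True)


def read_truth(area_path, stratum_path) -> TruePrevalence:
    area = pd.read_csv(area_path, dtype={"area": str}, float_precision="round_trip").set_index("area")
    stratum = pd.read_csv(
        stratum_path, dtype={"area": str, "stratum": str}, float_precision="round_trip"
    ).set_index(["area", "stratum"])
    return TruePrevalence(
        area=area.drop(columns=["b", "eta"]),
        stratum=stratum,
        b=area["b"],
        eta=area["eta"],
        params=None,
    )


def write_direct(direct: pd.DataFrame, path) -> None:
    direct.to_csv(path, index=False)


def read_direct(path) -> pd.DataFrame:
    t = pd.read_csv(path, dtype={"area": str}, float_precision="round_trip")
    need = {"area", "n_obs", "p_hat", "var_p", "logit_mean", "logit_var", "degenerate"}
    missing = need - set(t.columns)
    if missing:
        raise ValueError(f"direct-estimates table lacks columns {sorted(missing)}")
    return t


def write_draws(draws: np.ndarray, area_ids, path) -> None:
    """Posterior draws as a wide table: one row per draw, one column per area."""
    pd.DataFrame(draws, columns=[str(a) for a in area_ids]).to_csv(path, index=False)


def read_draws(path) -> tuple:
    t = pd.read_csv(path, float_precision="round_trip")
    return t.to_numpy(dtype=float), tuple(t.columns)


def write_composition(comp: CategoryComposition, directory, prefix="composition") -> None:
    d = Path(directory)
    for cat in CATEGORIES:
        write_draws(comp.draws[cat], comp.area_ids, d / f"{prefix}_{cat}_draws.csv")


def read_composition(directory, prefix="composition") -> CategoryComposition:
    d = Path(directory)
    draws = {}
    ids = None
    for cat in CATEGORIES:
        arr, cols = read_draws(d / f"{prefix}_{cat}_draws.csv")
        draws[cat] = arr
        ids = cols
    return CategoryComposition(area_ids=ids, draws=draws)
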