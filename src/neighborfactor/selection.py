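"""Feature selection for wide tract tables.

Three rules reduce the raw variable set to the analysis set, applied in
order: (1) drop variables declared redundant (complements of a retained
variable, e.g. the female share is the inverse of the male share), (2) drop
variables whose coefficient of variation across tracts falls below a
threshold (default 0.06), and (3) collapse strata/subgroup columns (age
bands, degree levels, ...) into single statistics via a per-group combine
rule. Redundancy and strata membership are declared in a variable catalog
rather than auto-detected: the catalog is the explicit, auditable record of
which columns are definitionally linked.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd

DEFAULT_CV_THRESHOLD = 0.06


class SelectionResult(NamedTuple):
    table: pd.DataFrame
    log: pd.DataFrame  # columns: variable, action, detail


def _data_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c != "GEOID"]


def _catalog_map(catalog: pd.DataFrame) -> pd.DataFrame:
    cat = catalog.fillna("")
    return cat.set_index("variable", drop=False)


def drop_redundant(table: pd.DataFrame, catalog: pd.DataFrame) -> SelectionResult:
    """Remove catalog-declared redundant (complement) columns.

    A column is removed when its catalog role is ``complement`` or it has
    ``complement_of`` set; the log records the retained counterpart. A
    complement whose counterpart is itself removed is a circular redundancy
    and raises.
    """
    cat = _catalog_map(catalog)
    cols = _data_columns(table)
    missing = [c for c in cols if c not in cat.index]
    if missing:
        raise ValueError(f"catalog does not cover columns: {missing}")

    removed, log_rows = [], []
    for c in cols:
        row = cat.loc[c]
        if row["role"] == "complement" or row.get("complement_of", ""):
            removed.append(c)
            log_rows.append(
                {"variable": c, "action": "redundant",
                 "detail": f"retained:{row.get('complement_of', '')}"}
            )
    removed_set = set(removed)
    for r in log_rows:
        kept = r["detail"].split(":", 1)[1]
        if kept in removed_set:
            raise ValueError(
                f"circular redundancy: {r['variable']} points at removed column {kept}"
            )
    out = table.drop(columns=removed)
    return SelectionResult(out, pd.DataFrame(log_rows, columns=["variable", "action", "detail"]))


def filter_low_cv(
    table: pd.DataFrame,
    threshold: float = DEFAULT_CV_THRESHOLD,
    *,
    ddof: int = 1,
) -> SelectionResult:
    """Remove columns whose coefficient of variation falls below ``threshold``.

    CV = sample standard deviation / mean, computed on raw values ignoring
    missing entries. Columns with non-positive mean have no defined CV and
    are always retained (logged as such).
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    cols = _data_columns(table)
    if not cols:
        raise ValueError("table has no data columns")

    removed, log_rows = [], []
    for c in cols:
        x = table[c].to_numpy(dtype=float)
        x = x[~np.isnan(x)]
        mean = x.mean()
        if mean <= 0:
            log_rows.append(
                {"variable": c, "action": "kept", "detail": "cv-undefined, retained"}
            )
            continue
        cv = x.std(ddof=ddof) / mean
        if cv < threshold:
            removed.append(c)
            log_rows.append(
                {"variable": c, "action": "low_cv", "detail": f"cv={cv:.6g}"}
            )
    out = table.drop(columns=removed)
    return SelectionResult(out, pd.DataFrame(log_rows, columns=["variable", "action", "detail"]))


def combine_strata(table: pd.DataFrame, catalog: pd.DataFrame) -> SelectionResult:
    """Collapse each stratum group into a single parent column.

    Proportion subgroups combine by ``sum`` (e.g. share with at least a
    bachelor's degree = sum of degree-level shares); ordered bins combine by
    ``weighted_mean`` with bin-midpoint weights (e.g. mean age from age-band
    shares). Missing values in any subgroup propagate to the combined value.
    """
    cat = _catalog_map(catalog)
    strata = cat[cat["role"] == "stratum"]
    out = table.copy()
    log_rows = []
    for parent, grp in strata.groupby("parent"):
        members = [m for m in grp["variable"] if m in out.columns]
        if not members:
            continue
        if len(members) < len(grp):
            raise ValueError(f"stratum group {parent!r} is only partially present")
        rules = set(grp["combine_rule"])
        if len(rules) != 1:
            raise ValueError(f"stratum group {parent!r} has mixed combine rules")
        rule = rules.pop()
        block = out[members].to_numpy(dtype=float)
        if rule == "sum":
            combined = block.sum(axis=1)
        elif rule == "weighted_mean":
            weights = _parse_weights(grp)
            if len(weights) != len(members):
                raise ValueError(
                    f"stratum group {parent!r}: {len(weights)} weights for "
                    f"{len(members)} subgroup columns"
                )
            combined = block @ np.asarray(weights, dtype=float)
        else:
            raise ValueError(f"unknown combine rule {rule!r} for {parent!r}")
        combined[np.isnan(block).any(axis=1)] = np.nan
        out = out.drop(columns=members)
        out[parent] = combined
        log_rows.extend(
            {"variable": m, "action": "combined_into", "detail": parent}
            for m in members
        )
    return SelectionResult(out, pd.DataFrame(log_rows, columns=["variable", "action", "detail"]))


def _parse_weights(grp: pd.DataFrame) -> list[float]:
    if "weight" not in grp.columns:
        raise ValueError("weighted_mean strata need a 'weight' catalog column")
    return [float(w) for w in grp["weight"]]


def select_features(
    table: pd.DataFrame,
    catalog: pd.DataFrame,
    cv_threshold: float = DEFAULT_CV_THRESHOLD,
) -> SelectionResult:
    """Run the full selection pipeline: redundancy -> low CV -> strata.

    The concatenated logs account exactly for the difference between input
    and output column counts.
    """
    t1, log1 = drop_redundant(table, catalog)
    t2, log2 = filter_low_cv(t1, cv_threshold)
    t3, log3 = combine_strata(t2, catalog)
    log = pd.concat([log1, log2, log3], ignore_index=True)
    return SelectionResult(t3, log)
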