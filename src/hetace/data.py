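"""Twin-pair ordinal item data: container, I/O and descriptive checks.

The observed input is a table with one row per twin individual (or per
individual-occasion before occasion selection): pair identifier, member
index (1/2), zygosity (MZ/DZ), sex (M/F), age in years, survey occasion
and a fixed roster of 3-category item scores (0/1/2, NA for missing).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("hetace")

__all__ = [
    "TwinDataset",
    "DEFAULT_ROSTER",
    "read_twin_table",
    "write_twin_table",
    "select_analysis_vector",
    "cronbach_alpha",
    "summarize_pairs",
]

DEFAULT_ROSTER: tuple[str, ...] = tuple(f"item{i:02d}" for i in range(1, 14))
META_COLUMNS = ("pair_id", "member", "zygosity", "sex", "age", "occasion")


class SchemaError(ValueError):
    """Malformed column set or codes in a twin table."""


class PairingError(ValueError):
    """Twin-pair structure violated (singleton pair, bad member indices...)."""


@dataclass
class TwinDataset:
    """Validated twin-pair item-response table.

    ``table`` holds one row per individual (after occasion selection) or
    per individual-occasion, with metadata columns
    ``pair_id, member, zygosity, sex, age, occasion`` followed by the
    item roster; item scores are pandas nullable integers in {0, 1, 2}.
    """

    table: pd.DataFrame
    roster: tuple[str, ...] = DEFAULT_ROSTER
    multi_occasion: bool = False

    def __post_init__(self) -> None:
        self.roster = tuple(self.roster)
        self.table = self.table.reset_index(drop=True)
        self._validate()

    def _validate(self) -> None:
        df = self.table
        missing_cols = [c for c in (*META_COLUMNS, *self.roster) if c not in df.columns]
        if missing_cols:
            raise SchemaError(f"missing columns: {missing_cols}")
        bad_zyg = ~df["zygosity"].isin(["MZ", "DZ"])
        if bad_zyg.any():
            raise SchemaError(f"malformed zygosity code at row {int(np.nonzero(bad_zyg.to_numpy())[0][0])}")
        bad_sex = ~df["sex"].isin(["M", "F"])
        if bad_sex.any():
            raise SchemaError(f"malformed sex code at row {int(np.nonzero(bad_sex.to_numpy())[0][0])}")
        for col in self.roster:
            vals = df[col]
            ok = vals.isna() | vals.isin([0, 1, 2])
            if not ok.all():
                raise ValueError(f"response outside {{0,1,2}} in column {col}")
            df[col] = vals.astype("Int64")
        per = df.drop_duplicates(["pair_id", "member"])
        agg = per.groupby("pair_id").agg(
            n=("member", "size"),
            mmin=("member", "min"),
            mmax=("member", "max"),
            nzyg=("zygosity", "nunique"),
            zyg=("zygosity", "first"),
            nsex=("sex", "nunique"),
        )
        bad = agg.index[(agg["n"] != 2) | (agg["mmin"] != 1) | (agg["mmax"] != 2)]
        if len(bad):
            raise PairingError(f"pair {bad[0]!r} must have exactly members {{1,2}}")
        bad = agg.index[agg["nzyg"] != 1]
        if len(bad):
            raise PairingError(f"pair {bad[0]!r} has inconsistent zygosity")
        bad = agg.index[(agg["zyg"] == "MZ") & (agg["nsex"] == 2)]
        if len(bad):
            raise PairingError(f"opposite-sex members in MZ pair {bad[0]!r}")
        sort_keys = ["pair_id", "member"] + (["occasion"] if self.multi_occasion else [])
        self.table = df.sort_values(sort_keys, kind="mergesort").reset_index(drop=True)

    # -- convenience accessors -------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.table.drop_duplicates(["pair_id", "member"]))

    @property
    def n_pairs(self) -> int:
        return self.table["pair_id"].nunique()

    @property
    def n_missing(self) -> int:
        return int(self.table[list(self.roster)].isna().to_numpy().sum())

    def responses(self) -> np.ndarray:
        """Item scores as float array (NaN for missing), rows as in ``table``."""
        return self.table[list(self.roster)].to_numpy(dtype=float, na_value=np.nan)

    def pair_arrays(self):
        """Index arrays for pair-structured computation.

        Returns dict with ``member1``/``member2`` row indices per pair
        (aligned), pair ``zygosity`` codes and per-row ``female`` codes.
        """
        df = self.table
        idx1 = df.index[df["member"] == 1].to_numpy()
        idx2 = df.index[df["member"] == 2].to_numpy()
        assert np.array_equal(df.loc[idx1, "pair_id"].to_numpy(), df.loc[idx2, "pair_id"].to_numpy())
        return {
            "member1": idx1,
            "member2": idx2,
            "is_mz": (df.loc[idx1, "zygosity"] == "MZ").to_numpy(),
            "female": (df["sex"] == "F").to_numpy().astype(float),
        }

    def subset_items(self, keep: list[str]) -> "TwinDataset":
        cols = list(META_COLUMNS) + list(keep)
        return TwinDataset(self.table[cols].copy(), roster=tuple(keep), multi_occasion=self.multi_occasion)

    def subset_pairs(self, pair_ids) -> "TwinDataset":
        mask = self.table["pair_id"].isin(list(pair_ids))
        return TwinDataset(self.table[mask].copy(), roster=self.roster, multi_occasion=self.multi_occasion)


def read_twin_table(path, roster=DEFAULT_ROSTER, *, one_based_scores: bool = False, multi_occasion: bool = False) -> TwinDataset:
    """Read and validate a twin-pair CSV.

    Expects columns ``pair_id, member, zygosity, sex, age, occasion``
    plus the roster; ``NA`` (empty cell) marks missing responses.
    ``one_based_scores=True`` accepts the 1/2/3 coding dialect and
    shifts it to the internal 0/1/2 scale.
    """
    df = pd.read_csv(path, comment="#")
    missing_cols = [c for c in (*META_COLUMNS, *roster) if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"missing columns: {missing_cols}")
    for col in roster:
        df[col] = pd.array(df[col], dtype="Int64")
        if one_based_scores:
            df[col] = df[col] - 1
    return TwinDataset(df, roster=tuple(roster), multi_occasion=multi_occasion)


def write_twin_table(dataset: TwinDataset, path) -> None:
    """Write the dataset back to CSV with NA for missing (round-trip safe)."""
    cols = list(META_COLUMNS) + list(dataset.roster)
    dataset.table[cols].to_csv(path, index=False, na_rep="NA")


def select_analysis_vector(dataset: TwinDataset) -> TwinDataset:
    """Pick one occasion per individual: fewest missing items, earliest wins ties.

    Individuals whose every occasion is entirely missing are dropped
    with a logged warning.  Co-twins may legitimately resolve to
    different occasions; pairs left as singletons after dropping are
    removed entirely.
    """
    df = dataset.table
    roster = list(dataset.roster)
    n_missing = df[roster].isna().sum(axis=1)
    work = df.assign(_miss=n_missing)
    keep_rows: list[int] = []
    dropped: list[tuple] = []
    for (pid, member), grp in work.groupby(["pair_id", "member"], sort=False):
        grp = grp.sort_values(["_miss", "occasion"], kind="mergesort")
        best = grp.iloc[0]
        if best["_miss"] == len(roster):
            dropped.append((pid, member))
            continue
        keep_rows.append(best.name)
    if dropped:
        logger.warning("dropped %d individual(s) with all-missing occasions: %s", len(dropped), dropped)
        warnings.warn(f"dropped {len(dropped)} individual(s) with all-missing occasions", stacklevel=2)
    out = df.loc[sorted(keep_rows)].drop(columns=[], errors="ignore").copy()
    # remove pairs reduced to a single member
    sizes = out.groupby("pair_id")["member"].transform("size")
    out = out[sizes == 2]
    return TwinDataset(out, roster=dataset.roster, multi_occasion=False)


def cronbach_alpha(responses) -> float:
    """Cronbach's alpha over complete cases.

    ``k/(k-1) * (1 - sum of item variances / variance of the total
    score)``, a lower bound on reliability for a sum score over k items.
    Accepts a 2-D array or DataFrame (rows = individuals).
    """
    mat = np.asarray(pd.DataFrame(responses).to_numpy(dtype=float, na_value=np.nan))
    mat = mat[~np.isnan(mat).any(axis=1)]
    if mat.shape[1] < 2 or mat.shape[0] < 2:
        raise ValueError("need >= 2 items and >= 2 complete rows")
    item_var = mat.var(axis=0, ddof=1)
    total_var = mat.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ZeroDivisionError("total-score variance is zero; alpha undefined")
    k = mat.shape[1]
    return k / (k - 1) * (1.0 - item_var.sum() / total_var)


def _pair_cell(zyg: str, sexes: frozenset) -> str:
    if len(sexes) == 2:
        return f"{zyg}-OS"
    (sex,) = sexes
    return f"{zyg}-{'male' if sex == 'M' else 'female'}"


def summarize_pairs(dataset: TwinDataset, by: list[str] | None = None) -> pd.DataFrame:
    """Pair counts by zygosity x sex-composition (x optional grouping keys).

    Returns a table with ``n_pairs`` (any data) and ``n_complete``
    (pairs whose two members answered every roster item).
    """
    df = dataset.table
    roster = list(dataset.roster)
    by = list(by or [])
    rows = []
    for pid, grp in df.groupby("pair_id"):
        cell = _pair_cell(grp["zygosity"].iloc[0], frozenset(grp["sex"])) if len(grp) else None
        complete = not grp[roster].isna().to_numpy().any()
        rec = {"cell": cell, "complete": complete}
        for key in by:
            rec[key] = grp[key].iloc[0]
        rows.append(rec)
    if not rows:
        cells = ["MZ-male", "MZ-female", "DZ-male", "DZ-female", "DZ-OS"]
        return pd.DataFrame({"cell": cells, "n_pairs": 0, "n_complete": 0})
    pairs = pd.DataFrame(rows)
    keys = by + ["cell"]
    out = (
        pairs.groupby(keys)
        .agg(n_pairs=("complete", "size"), n_complete=("complete", "sum"))
        .reset_index()
    )
    out["n_complete"] = out["n_complete"].astype(int)
    return out
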