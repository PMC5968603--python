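"""Synthetic matching: exact-cell hot-deck donor imputation.

Every survey person is matched to a donor carrying a weekly economic
profile (earnings, other income, welfare, tax) on ten categorical
variables. Matching is exact on the full ten-variable cell; when a
recipient's cell holds no donor, variables are dropped one at a time in a
configured fallback order (never the labour-force status stratifier) until
a donor appears. Ties within a cell are broken by a seeded uniform draw.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import FallbackPolicy
from .synthetic import ECON_COLUMNS, MATCH_COLUMNS

__all__ = [
    "MATCH_COLUMNS",
    "build_match_key",
    "impute_economics",
    "UnmatchedRecipientError",
]

_NULL_HOURS = "none"  # sentinel: hours band of the non-employed


class UnmatchedRecipientError(LookupError):
    """No donor found even after exhausting the fallback ladder."""

    def __init__(self, key):
        self.key = key
        super().__init__(f"no donor for recipient cell {key!r} after full fallback")


def build_match_key(person) -> tuple:
    """Project a person record onto the ordered ten-variable match key.

    ``person`` is a mapping (Series or dict). A null hours band (the
    non-employed) maps to a sentinel category; any other null raises.
    """
    key = []
    for var in MATCH_COLUMNS:
        try:
            val = person[var]
        except KeyError:
            raise KeyError(f"person record lacks matching variable {var!r}") from None
        if pd.isna(val):
            if var == "hours_band":
                val = _NULL_HOURS
            else:
                raise ValueError(f"matching variable {var!r} is null")
        if isinstance(val, np.generic):  # plain scalars so keys serialise cleanly
            val = val.item()
        key.append(val)
    return tuple(key)


def _key_frame(df: pd.DataFrame) -> pd.DataFrame:
    missing = [v for v in MATCH_COLUMNS if v not in df.columns]
    if missing:
        raise KeyError(f"table lacks matching variables {missing}")
    keys = df[MATCH_COLUMNS].copy()
    keys["hours_band"] = keys["hours_band"].fillna(_NULL_HOURS)
    for var in MATCH_COLUMNS:
        if var != "hours_band" and keys[var].isna().any():
            raise ValueError(f"matching variable {var!r} is null for some records")
    return keys


def impute_economics(
    recipients: pd.DataFrame,
    donors: pd.DataFrame,
    policy: FallbackPolicy | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Attach a donor economic profile to every recipient.

    Parameters
    ----------
    recipients : DataFrame
        Person table carrying the ten matching variables.
    donors : DataFrame
        Donor table carrying the matching variables and the weekly
        economic columns.
    policy : FallbackPolicy, optional
        Order in which variables are dropped for empty cells.
    seed : int
        Controls the uniform tie-break among multiple donors in a cell.

    Returns
    -------
    (imputed, audit)
        ``imputed`` is the recipient table with the economic columns
        appended; ``audit`` records per recipient the fallback depth and
        the donor row index used.

    Raises
    ------
    UnmatchedRecipientError
        If some recipient has no donor even on the shortest key.
    """
    if len(donors) == 0:
        raise ValueError("donor pool is empty")
    policy = policy or FallbackPolicy()
    rng = np.random.default_rng(seed)

    rkeys = _key_frame(recipients).reset_index(drop=True)
    dkeys = _key_frame(donors).reset_index(drop=True)

    n = len(rkeys)
    donor_row = np.full(n, -1, dtype=np.int64)
    depth_used = np.full(n, -1, dtype=np.int64)
    unmatched = np.ones(n, dtype=bool)
    # one tie-break draw per recipient, fixed across ladder steps
    u = rng.random(n)

    for depth in range(len(policy.drop_order) + 1):
        if not unmatched.any():
            break
        dropped = set(policy.drop_order[:depth])
        vars_d = [v for v in MATCH_COLUMNS if v not in dropped]
        groups = dkeys.groupby(vars_d, sort=True, dropna=False).indices
        idx = np.flatnonzero(unmatched)
        sub = rkeys.iloc[idx]
        cell_keys = list(map(tuple, sub[vars_d].itertuples(index=False, name=None)))
        for i, key in zip(idx, cell_keys):
            rows = groups.get(key if len(vars_d) > 1 else key[0])
            if rows is not None and len(rows):
                donor_row[i] = rows[int(u[i] * len(rows))]
                depth_used[i] = depth
                unmatched[i] = False

    if unmatched.any():
        i = int(np.flatnonzero(unmatched)[0])
        raise UnmatchedRecipientError(build_match_key(recipients.iloc[i]))

    imputed = recipients.copy()
    econ = donors.iloc[donor_row][ECON_COLUMNS].reset_index(drop=True)
    econ.index = imputed.index
    for col in ECON_COLUMNS:
        imputed[col] = econ[col]

    audit = pd.DataFrame(
        {
            "recipient_index": np.arange(n),
            "fallback_depth": depth_used,
            "donor_row": donor_row,
        }
    )
    if "record_id" in recipients.columns:
        audit.insert(0, "record_id", recipients["record_id"].to_numpy())
    return imputed, audit
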