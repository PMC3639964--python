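"""Goodness-of-fit tests for the Cormack-Jolly-Seber model.

Implements the classical contingency-table decomposition used by RELEASE and
U-CARE: per-occasion tables for

* TEST3.SR — do newly marked and previously marked animals seen at occasion t
  differ in whether they are ever seen again (transience)?
* TEST3.SM — among animals seen at t and seen again, does the occasion of the
  next sighting differ between newly and previously marked animals?
* TEST2.CT — among animals known to be alive at t and t+1, does capture at t
  predict capture at t+1 (trap-dependence)?
* TEST2.CL — among animals known alive around t+1 but not captured then, does
  capture at t predict when they are next captured?

Component chi-squares are summed over occasions after pooling cells until
every expected count is at least 2 (degrees of freedom recomputed after
pooling; tables that cannot reach the threshold are dropped).  TEST3.SR and
TEST2.CT additionally report a signed z statistic: the per-table standardised
deviations (hypergeometric variance) are summed and divided by the square
root of the number of informative tables, oriented so that transience
("new animals reseen less") and trap-happiness ("capture at t predicts
capture at t+1") are positive.

The overall statistic sums the four components; the overdispersion factor is
c-hat = chi2 / df.  Exact numerical agreement with U-CARE's (undocumented)
pooling is not claimed; hand-oracle equality on unpooled tables and correct
null behaviour are the contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .scenarios import CaptureHistoryMatrix

__all__ = [
    "MArray",
    "ComponentResult",
    "GOFReport",
    "build_marray",
    "test3_sr",
    "test3_sm",
    "test2_ct",
    "test2_cl",
    "overall_gof",
]

MIN_EXPECTED = 2.0


@dataclass
class MArray:
    """Reduced m-array of a capture-history dataset.

    ``releases[t]`` counts animals released (newly marked or re-released
    after a detection) at occasion t; ``m[t, j]`` counts those next detected
    at occasion j > t; ``never_recaptured[t]`` those never detected again.
    Indices are 0-based occasions; row K-1 is structurally empty.
    """

    releases: np.ndarray
    m: np.ndarray
    never_recaptured: np.ndarray

    def __post_init__(self) -> None:
        k = self.releases.size
        if self.m.shape != (k, k):
            raise ValueError("m must be square with one row per occasion")
        if np.any(np.tril(self.m, k=0) != 0):
            raise ValueError("m[t, j] must be 0 for j <= t")
        if not np.array_equal(self.m.sum(axis=1) + self.never_recaptured, self.releases):
            raise ValueError("m-array rows must sum to the releases")

    @property
    def n_occasions(self) -> int:
        return self.releases.size


def build_marray(data: CaptureHistoryMatrix) -> MArray:
    """Standard CJS m-array; every detection is a release for the next interval."""
    y = data.detections
    n, k = y.shape
    releases = np.zeros(k, dtype=np.int64)
    m = np.zeros((k, k), dtype=np.int64)
    for i in range(n):
        occs = np.flatnonzero(y[i])
        for a, b in zip(occs[:-1], occs[1:]):
            m[a, b] += 1
        for a in occs[:-1]:
            releases[a] += 1
        if occs.size and occs[-1] < k - 1:
            releases[occs[-1]] += 1
    never = releases - m.sum(axis=1)
    # animals last seen at the final occasion are not releases (no interval follows)
    return MArray(releases=releases, m=m, never_recaptured=never)


@dataclass
class ComponentResult:
    """One GOF component: pooled chi-square, df, p, optional directional z."""

    name: str
    chi2: float
    df: int
    p: float
    z: Optional[float] = None
    p_z: Optional[float] = None
    n_tables: int = 0
    degenerate: bool = False

    def as_dict(self) -> dict:
        return dict(
            component=self.name, chi2=self.chi2, df=self.df, p=self.p,
            z=self.z, p_z=self.p_z, n_tables=self.n_tables, degenerate=self.degenerate,
        )


def _drop_empty(table: np.ndarray) -> np.ndarray:
    table = table[table.sum(axis=1) > 0]
    if table.size:
        table = table[:, table.sum(axis=0) > 0]
    return table


def _expected(table: np.ndarray) -> np.ndarray:
    total = table.sum()
    return np.outer(table.sum(axis=1), table.sum(axis=0)) / total


def _pool_columns(table: np.ndarray, min_expected: float = MIN_EXPECTED) -> np.ndarray:
    """Merge adjacent columns (smallest-total first) until all expected counts
    reach ``min_expected`` or only two columns remain."""
    table = _drop_empty(np.asarray(table, dtype=float))
    while table.ndim == 2 and table.shape[1] > 2 and (_expected(table) < min_expected).any():
        totals = table.sum(axis=0)
        j = int(np.argmin(totals))
        k = j + 1 if j + 1 < table.shape[1] else j - 1
        table[:, k] += table[:, j]
        table = np.delete(table, j, axis=1)
    return table


def _pearson_chi2(table: np.ndarray) -> tuple[float, int]:
    """Pearson chi-square and df of an r x c table (no continuity correction)."""
    table = _drop_empty(np.asarray(table, dtype=float))
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        return 0.0, 0
    exp = _expected(table)
    chi2 = float(((table - exp) ** 2 / exp).sum())
    df = (table.shape[0] - 1) * (table.shape[1] - 1)
    return chi2, df


def _table_ok(table: np.ndarray, min_expected: float = MIN_EXPECTED) -> bool:
    table = _drop_empty(np.asarray(table, dtype=float))
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        return False
    return bool((_expected(table) >= min_expected).all())


def _signed_z(table: np.ndarray) -> Optional[float]:
    """Standardised deviation of cell (0, 0) of a 2x2 table under the
    hypergeometric null; positive when the observed count exceeds expectation."""
    t = np.asarray(table, dtype=float)
    n = t.sum()
    r = t.sum(axis=1)
    c = t.sum(axis=0)
    if n < 2 or r.min() == 0 or c.min() == 0:
        return None
    var = r[0] * r[1] * c[0] * c[1] / (n * n * (n - 1.0))
    if var <= 0:
        return None
    return float((t[0, 0] - r[0] * c[0] / n) / np.sqrt(var))


def _finish_component(
    name: str, chi2: float, df: int, zs: list[float]
) -> ComponentResult:
    degenerate = df == 0
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else float("nan")
    z = p_z = None
    if zs:
        z = float(np.sum(zs) / np.sqrt(len(zs)))
        p_z = float(2.0 * stats.norm.sf(abs(z)))
    return ComponentResult(
        name=name, chi2=chi2, df=df, p=p, z=z, p_z=p_z,
        n_tables=len(zs) if zs else 0, degenerate=degenerate,
    )


def _seen_after(y: np.ndarray) -> np.ndarray:
    """seen_after[i, t] is True when individual i is detected at any occasion > t."""
    rev_any = np.cumsum(y[:, ::-1], axis=1)[:, ::-1] > 0
    out = np.zeros_like(y, dtype=bool)
    out[:, :-1] = rev_any[:, 1:]
    return out


def test3_sr(data: CaptureHistoryMatrix) -> ComponentResult:
    """TEST3.SR: newly vs previously marked animals seen at t, split by
    whether they are ever seen after t.  Signed z is positive for transience
    (new animals reseen less often)."""
    y = data.detections.astype(bool)
    first = data.first_capture
    n, k = y.shape
    if k < 3:
        raise ValueError("TEST3.SR requires at least 3 occasions")
    seen_after = _seen_after(data.detections)
    chi2_total, df_total = 0.0, 0
    zs: list[float] = []
    for t in range(1, k - 1):
        at_t = y[:, t]
        new = at_t & (first == t)
        old = at_t & (first < t)
        # rows: new / old; cols: reseen after t / never reseen
        table = np.array(
            [
                [np.sum(new & seen_after[:, t]), np.sum(new & ~seen_after[:, t])],
                [np.sum(old & seen_after[:, t]), np.sum(old & ~seen_after[:, t])],
            ],
            dtype=float,
        )
        z = _signed_z(table)
        if z is not None:
            # transience: new animals reseen less => observed (new, reseen) below expectation
            zs.append(-z)
        if _table_ok(table):
            c, d = _pearson_chi2(table)
            chi2_total += c
            df_total += d
    return _finish_component("TEST3.SR", chi2_total, df_total, zs)


def test3_sm(data: CaptureHistoryMatrix) -> ComponentResult:
    """TEST3.SM: among animals seen at t and seen again, compare the occasion
    of next sighting between newly and previously marked animals."""
    y = data.detections.astype(bool)
    first = data.first_capture
    n, k = y.shape
    if k < 3:
        raise ValueError("TEST3.SM requires at least 3 occasions")
    seen_after = _seen_after(data.detections)
    next_occ = _next_detection(data.detections)
    chi2_total, df_total = 0.0, 0
    n_tables = 0
    for t in range(1, k - 1):
        sel = y[:, t] & seen_after[:, t]
        if not sel.any():
            continue
        new = first[sel] == t
        nxt = next_occ[sel, t]
        cols = np.arange(t + 1, k)
        table = np.zeros((2, cols.size))
        for row, mask in enumerate((new, ~new)):
            if mask.any():
                table[row] = np.bincount(nxt[mask] - (t + 1), minlength=cols.size)
        table = _pool_columns(table)
        if _table_ok(table):
            c, d = _pearson_chi2(table)
            chi2_total += c
            df_total += d
            n_tables += 1
    res = _finish_component("TEST3.SM", chi2_total, df_total, [])
    res.n_tables = n_tables
    return res


def _next_detection(y: np.ndarray) -> np.ndarray:
    """next_detection[i, t] is the first occasion > t at which i is detected
    (k when none)."""
    n, k = y.shape
    out = np.full((n, k), k, dtype=np.int64)
    for t in range(k - 2, -1, -1):
        out[:, t] = np.where(y[:, t + 1] == 1, t + 1, out[:, t + 1])
    return out


def test2_ct(data: CaptureHistoryMatrix) -> ComponentResult:
    """TEST2.CT: among animals marked by t and known alive at t+1 (seen at or
    after t+1), cross-classify capture at t by capture at t+1.  Signed z is
    positive for trap-happiness."""
    y = data.detections.astype(bool)
    first = data.first_capture
    n, k = y.shape
    if k < 3:
        raise ValueError("TEST2.CT requires at least 3 occasions")
    seen_after = _seen_after(data.detections)
    chi2_total, df_total = 0.0, 0
    zs: list[float] = []
    for t in range(k - 1):
        alive_next = y[:, t + 1] | seen_after[:, t + 1]
        sel = (first <= t) & alive_next
        if not sel.any():
            continue
        at_t = y[sel, t]
        at_next = y[sel, t + 1]
        # rows: caught at t / not; cols: caught at t+1 / not
        table = np.array(
            [
                [np.sum(at_t & at_next), np.sum(at_t & ~at_next)],
                [np.sum(~at_t & at_next), np.sum(~at_t & ~at_next)],
            ],
            dtype=float,
        )
        z = _signed_z(table)
        if z is not None:
            zs.append(z)  # (caught t, caught t+1) above expectation => trap-happy
        if _table_ok(table):
            c, d = _pearson_chi2(table)
            chi2_total += c
            df_total += d
    return _finish_component("TEST2.CT", chi2_total, df_total, zs)


def test2_cl(data: CaptureHistoryMatrix) -> ComponentResult:
    """TEST2.CL: among animals marked by t, missed at t+1 but seen later,
    compare the occasion of next sighting between those caught and not caught
    at t."""
    y = data.detections.astype(bool)
    first = data.first_capture
    n, k = y.shape
    if k < 3:
        raise ValueError("TEST2.CL requires at least 3 occasions")
    seen_after = _seen_after(data.detections)
    next_occ = _next_detection(data.detections)
    chi2_total, df_total = 0.0, 0
    n_tables = 0
    for t in range(k - 2):
        sel = (first <= t) & ~y[:, t + 1] & seen_after[:, t + 1]
        if not sel.any():
            continue
        at_t = y[sel, t]
        nxt = next_occ[sel, t + 1]
        cols = np.arange(t + 2, k)
        table = np.zeros((2, cols.size))
        for row, mask in enumerate((at_t, ~at_t)):
            if mask.any():
                table[row] = np.bincount(nxt[mask] - (t + 2), minlength=cols.size)
        table = _pool_columns(table)
        if _table_ok(table):
            c, d = _pearson_chi2(table)
            chi2_total += c
            df_total += d
            n_tables += 1
    res = _finish_component("TEST2.CL", chi2_total, df_total, [])
    res.n_tables = n_tables
    return res


@dataclass
class GOFReport:
    """Combined CJS goodness-of-fit report.

    The overall chi-square and df are the sums over the four components;
    ``c_hat = chi2 / df`` when df > 0 (NaN and flagged otherwise)."""

    components: dict[str, ComponentResult]
    marray: MArray
    chi2: float = field(init=False)
    df: int = field(init=False)
    p: float = field(init=False)
    c_hat: float = field(init=False)
    degenerate: bool = field(init=False)

    def __post_init__(self) -> None:
        self.chi2 = float(sum(c.chi2 for c in self.components.values()))
        self.df = int(sum(c.df for c in self.components.values()))
        self.degenerate = self.df == 0
        self.p = float(stats.chi2.sf(self.chi2, self.df)) if self.df > 0 else float("nan")
        self.c_hat = self.chi2 / self.df if self.df > 0 else float("nan")


def overall_gof(data: CaptureHistoryMatrix) -> GOFReport:
    """Overall CJS GOF test: TEST3.SR + TEST3.SM + TEST2.CT + TEST2.CL."""
    components = {
        "TEST3.SR": test3_sr(data),
        "TEST3.SM": test3_sm(data),
        "TEST2.CT": test2_ct(data),
        "TEST2.CL": test2_cl(data),
    }
    return GOFReport(components=components, marray=build_marray(data))
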