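"""Fractional hot-deck imputation.

Rows are cross-classified into imputation cells by discretizing every
variable (observed sample-quantile bins for continuous variables, a dedicated
code for semicontinuous zeros, native levels for categoricals). Fully
observed rows are donors; rows with any missing cell are recipients. A
recipient's eligible donors are the donors matching its cell key on every
*observed* coordinate. When any recipient has fewer than M eligible donors,
cells are coarsened automatically: among all single merges of two codes of
one variable (adjacent codes for ordered variables, the two smallest-
frequency codes for nominal ones), apply the merge that maximizes the
minimum eligible-donor count, until every recipient has at least M donors.

Each recipient then receives M distinct donors from its cell (uniformly
without replacement when the cell is larger), with equal fractional weights
1/M; all of a recipient's missing variables are imputed jointly from the same
donor within each fractional record.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd

from .core import FractionalAssignment, ImputationError, ImputationResult
from .schema import MixedDataset


@dataclass
class CellAssignment:
    """Discretized cell keys: integer codes per (row, variable), -1 = missing."""

    codes: np.ndarray                 # (n, V) int64
    var_names: list[str]
    n_codes: list[int]
    kinds: list[str]                  # "ordered" or "nominal"
    donor: np.ndarray                 # bool, row fully observed
    merges: list[tuple[str, int, int]] = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)

    def copy(self) -> "CellAssignment":
        return CellAssignment(self.codes.copy(), list(self.var_names),
                              list(self.n_codes), list(self.kinds),
                              self.donor.copy(), list(self.merges),
                              dict(self.diagnostics))


def discretize(data: MixedDataset, n_bins: int = 3) -> CellAssignment:
    """Build cell codes for every variable.

    Continuous variables are cut at observed sample quantiles into ``n_bins``
    ordered codes (fewer if there are fewer distinct values, logged);
    semicontinuous zeros form their own code with the positive part
    quantile-cut above it; categorical variables keep their levels.
    """
    if n_bins < 2:
        raise ImputationError("n_bins must be >= 2")
    n = len(data)
    cols, n_codes, kinds = [], [], []
    reduced: dict[str, int] = {}
    for v in data.schema:
        x = data.data[v.name]
        obs = x.notna().to_numpy()
        codes = np.full(n, -1, dtype=np.int64)
        if v.is_categorical:
            codes[obs] = pd.Categorical(
                x[obs], categories=list(v.levels)
            ).codes.astype(np.int64)
            k = len(v.levels)
            kinds.append("nominal" if v.vtype == "nominal" else "ordered")
        else:
            vals = x.to_numpy(dtype=float)
            if v.vtype == "semicontinuous":
                pos = obs & (vals > 0)
                edges = _quantile_edges(vals[pos], n_bins)
                codes[obs & (vals == 0)] = 0
                codes[pos] = 1 + np.searchsorted(edges, vals[pos], side="left")
                k = len(edges) + 2
                if len(edges) + 1 < n_bins:
                    reduced[v.name] = len(edges) + 1
            else:
                edges = _quantile_edges(vals[obs], n_bins)
                codes[obs] = np.searchsorted(edges, vals[obs], side="left")
                k = len(edges) + 1
                if k < n_bins:
                    reduced[v.name] = k
            kinds.append("ordered")
        cols.append(codes)
        n_codes.append(k)
    codes = np.column_stack(cols)
    donor = (codes >= 0).all(axis=1)
    return CellAssignment(codes, data.names, n_codes, kinds, donor,
                          diagnostics={"bins_reduced": reduced})


def _quantile_edges(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Interior quantile cut points, deduplicated."""
    if len(values) == 0:
        return np.array([])
    qs = np.arange(1, n_bins) / n_bins
    return np.unique(np.quantile(values, qs))


def _donor_counts(assignment: CellAssignment, codes: np.ndarray | None = None) -> np.ndarray:
    """Eligible-donor count for every recipient (donors matching the
    recipient's observed cell-key entries).

    Matching is done in two stages: donors are radix-keyed and sorted on the
    columns that are observed for every row (the covariate block), giving each
    recipient a candidate donor range; the remaining (partially observed)
    columns are then compared pairwise, treating the recipient's missing
    entries as wildcards.
    """
    codes = assignment.codes if codes is None else codes
    donor = assignment.donor
    recip_rows = np.flatnonzero(~donor)
    if len(recip_rows) == 0:
        return np.array([])
    full_cols = np.flatnonzero((codes >= 0).all(axis=0))
    part_cols = np.setdiff1d(np.arange(codes.shape[1]), full_cols)
    d_rows = np.flatnonzero(donor)
    if len(full_cols):
        mult = np.cumprod(
            [1] + [assignment.n_codes[c] for c in full_cols[:-1]]
        ).astype(np.int64)
        d_key = codes[np.ix_(d_rows, full_cols)] @ mult
        r_key = codes[np.ix_(recip_rows, full_cols)] @ mult
    else:
        d_key = np.zeros(len(d_rows), dtype=np.int64)
        r_key = np.zeros(len(recip_rows), dtype=np.int64)
    order = np.argsort(d_key, kind="stable")
    d_sorted_key = d_key[order]
    lo = np.searchsorted(d_sorted_key, r_key, side="left")
    hi = np.searchsorted(d_sorted_key, r_key, side="right")
    lens = hi - lo
    if len(part_cols) == 0 or lens.sum() == 0:
        return lens.astype(float)
    if lens.sum() > 200_000:
        # coarse cells: candidate ranges are wide, pairwise comparison would
        # blow up — count by missingness pattern with sorted key lookups
        return _donor_counts_by_pattern(assignment, codes, recip_rows, donor)
    d_part = codes[np.ix_(d_rows[order], part_cols)]
    r_part = codes[np.ix_(recip_rows, part_cols)]
    counts = np.empty(len(recip_rows))
    # expand (recipient, candidate donor) pairs in blocks to bound memory
    block_budget = 4_000_000
    start = 0
    n_r = len(recip_rows)
    while start < n_r:
        stop = start + 1
        total = int(lens[start])
        while stop < n_r and total + lens[stop] <= block_budget:
            total += int(lens[stop])
            stop += 1
        idx = np.arange(start, stop)
        blens = lens[idx]
        rrep = np.repeat(idx, blens)
        if len(rrep) == 0:
            counts[idx] = 0.0
        else:
            offsets = np.concatenate([[0], np.cumsum(blens)[:-1]])
            dpos = np.repeat(lo[idx], blens) + (
                np.arange(int(blens.sum())) - np.repeat(offsets, blens)
            )
            rp = r_part[rrep]
            ok = ((rp < 0) | (rp == d_part[dpos])).all(axis=1)
            counts[idx] = np.bincount(rrep - start, weights=ok, minlength=stop - start)
        start = stop
    return counts


def _donor_counts_by_pattern(
    assignment: CellAssignment,
    codes: np.ndarray,
    recip_rows: np.ndarray,
    donor: np.ndarray,
) -> np.ndarray:
    """Donor counts grouped by recipient missingness pattern (one sorted key
    lookup per pattern)."""
    obs = codes[recip_rows] >= 0
    pat_key = obs @ (1 << np.arange(obs.shape[1], dtype=np.int64))
    counts = np.zeros(len(recip_rows))
    d_codes = codes[donor]
    for key in np.unique(pat_key):
        sel = pat_key == key
        cols = np.flatnonzero(obs[sel][0])
        if len(cols) == 0:
            counts[sel] = donor.sum()
            continue
        mult = np.cumprod(
            [1] + [assignment.n_codes[c] for c in cols[:-1]]
        ).astype(np.int64)
        d_keys = d_codes[:, cols] @ mult
        r_keys = codes[recip_rows[sel]][:, cols] @ mult
        uniq, cnt = np.unique(d_keys, return_counts=True)
        pos = np.searchsorted(uniq, r_keys)
        pos_clip = np.clip(pos, 0, len(uniq) - 1)
        match = (pos < len(uniq)) & (uniq[pos_clip] == r_keys)
        counts[sel] = np.where(match, cnt[pos_clip], 0)
    return counts


def _merge_candidates(assignment: CellAssignment) -> list[tuple[int, int, int]]:
    """All single merges: (var index, code_a, code_b) with code_a < code_b."""
    cands = []
    for j, (k, kind) in enumerate(zip(assignment.n_codes, assignment.kinds)):
        if k < 2:
            continue
        if kind == "ordered":
            cands.extend((j, c, c + 1) for c in range(k - 1))
        else:
            col = assignment.codes[:, j]
            freq = np.bincount(col[col >= 0], minlength=k)
            order = np.argsort(freq, kind="stable")
            a, b = sorted(order[:2])
            cands.append((j, int(a), int(b)))
    return cands


def _apply_merge(codes: np.ndarray, j: int, a: int, b: int) -> np.ndarray:
    """Merge code b into code a of variable j, keeping codes contiguous."""
    col = codes[:, j].copy()
    obs = col >= 0
    col[obs & (col == b)] = a
    col[obs & (col > b)] -= 1
    out = codes.copy()
    out[:, j] = col
    return out


def collapse_cells(assignment: CellAssignment, M: int) -> CellAssignment:
    """Coarsen cells until every recipient has >= M eligible donors.

    Each step applies the single merge maximizing the minimum eligible-donor
    count (ties broken by the fraction of recipients already satisfied, then
    by candidate order). Terminates: full collapse leaves one universal cell,
    where every donor matches every recipient. All merges are recorded.
    """
    if M < 1:
        raise ImputationError("M must be >= 1")
    a = assignment.copy()
    n_donors = int(a.donor.sum())
    if n_donors < M:
        raise ImputationError(
            f"only {n_donors} complete rows available for M={M}; reduce M first"
        )
    while True:
        counts = _donor_counts(a)
        if len(counts) == 0 or counts.min() >= M:
            return a
        best, best_score = None, None
        for (j, ca, cb) in _merge_candidates(a):
            trial = _apply_merge(a.codes, j, ca, cb)
            n_codes = list(a.n_codes)
            n_codes[j] -= 1
            tc = _donor_counts(
                CellAssignment(trial, a.var_names, n_codes, a.kinds, a.donor)
            )
            score = (float(tc.min()), float((tc >= M).mean()))
            if best_score is None or score > best_score:
                best, best_score = (j, ca, cb, trial), score
        j, ca, cb, merged = best
        a.codes = merged
        a.n_codes[j] -= 1
        a.merges.append((a.var_names[j], ca, cb))
    return a


def _eligible_donors(assignment: CellAssignment, recipient_row: int) -> np.ndarray:
    """Donor row indices matching the recipient on its observed entries."""
    codes = assignment.codes
    key = codes[recipient_row]
    cols = key >= 0
    donors = np.flatnonzero(assignment.donor)
    match = (codes[donors][:, cols] == key[cols]).all(axis=1)
    return donors[match]


def fhd_run(
    data: MixedDataset,
    seed: int,
    M: int = 5,
    n_bins: int = 3,
) -> ImputationResult:
    """Fractional hot-deck imputation with M donors per recipient.

    Returns a ``kind="fractional"`` result: the input dataset plus the donor
    assignment (equal weights 1/M). If fewer than M complete rows exist, M is
    reduced to that count (logged in diagnostics).
    """
    complete = data.data.notna().all(axis=1).to_numpy()
    n_complete = int(complete.sum())
    if n_complete == 0:
        raise ImputationError("fractional hot-deck needs at least one complete row")
    diagnostics: dict = {}
    if n_complete < M:
        diagnostics["M_reduced_from"] = M
        M = n_complete
    recipients = np.flatnonzero(~complete)
    if len(recipients) == 0:
        return ImputationResult(
            kind="fractional", method="fhd", completed=[data.copy()],
            fractional=FractionalAssignment({}, {}),
            diagnostics=diagnostics,
        )
    assignment = collapse_cells(discretize(data, n_bins=n_bins), M)
    diagnostics["merges"] = list(assignment.merges)
    diagnostics.update(assignment.diagnostics)

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    donors_map: dict[int, list[int]] = {}
    weights_map: dict[int, list[Fraction]] = {}
    w = Fraction(1, M)
    codes = assignment.codes
    donor_rows = np.flatnonzero(assignment.donor)
    obs = codes[recipients] >= 0
    pat_key = obs @ (1 << np.arange(obs.shape[1], dtype=np.int64))
    for key in np.unique(pat_key):
        sel = np.flatnonzero(pat_key == key)
        cols = np.flatnonzero(obs[sel[0]])
        if len(cols) == 0:
            sorted_donors, d_sorted = donor_rows, np.zeros(len(donor_rows), dtype=np.int64)
        else:
            mult = np.cumprod(
                [1] + [assignment.n_codes[c] for c in cols[:-1]]
            ).astype(np.int64)
            d_keys = codes[donor_rows][:, cols] @ mult
            order = np.argsort(d_keys, kind="stable")
            sorted_donors, d_sorted = donor_rows[order], d_keys[order]
        r_keys = (codes[recipients[sel]][:, cols] @ mult) if len(cols) else \
            np.zeros(len(sel), dtype=np.int64)
        left = np.searchsorted(d_sorted, r_keys, side="left")
        right = np.searchsorted(d_sorted, r_keys, side="right")
        for i, ridx in enumerate(recipients[sel]):
            pool = sorted_donors[left[i]:right[i]]
            if len(pool) < M:   # cannot happen post-collapse; guard for safety
                raise ImputationError(
                    f"recipient {ridx}: only {len(pool)} donors after collapse"
                )
            chosen = pool if len(pool) == M else rng.choice(pool, size=M, replace=False)
            donors_map[int(ridx)] = [int(d) for d in chosen]
            weights_map[int(ridx)] = [w] * M
    return ImputationResult(
        kind="fractional", method="fhd", completed=[data.copy()],
        fractional=FractionalAssignment(donors_map, weights_map),
        diagnostics=diagnostics,
    )


def to_long_frame(result: ImputationResult) -> pd.DataFrame:
    """Long-format serialization of a fractional assignment:
    (recipient_row, fractional_record, donor_row, weight)."""
    if result.kind != "fractional" or result.fractional is None:
        raise ImputationError("to_long_frame requires a fractional result")
    rows = []
    for r, donors in sorted(result.fractional.donors.items()):
        for k, d in enumerate(donors):
            rows.append((r, k, d, float(result.fractional.weights[r][k])))
    return pd.DataFrame(rows, columns=["recipient_row", "fractional_record",
                                       "donor_row", "weight"])
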