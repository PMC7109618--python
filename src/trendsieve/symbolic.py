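"""Symbolic temporal-pattern baseline: SAX/EWD abstraction and TIRP mining.

This implements the symbolic (categorical) comparison pipeline in the style
of the KarmaLego/KLS framework:

1. **Temporal abstraction** — per-window means are discretized into an
   alphabet of symbols, either by SAX (z-normalize per channel, cut at
   standard-normal quantiles into equal-probability bins) or by equal-width
   discretization (EWD) between the channel's min and max.  Runs of equal
   symbols merge into maximal symbolic intervals.
2. **TIRP mining** — frequent time-interval-related patterns (TIRPs) are
   mined with three abstract pairwise relations, disjunctions of Allen's
   relations: *before*, *overlaps*, *contains*.  Size-2 patterns are found
   by exhaustive pair enumeration (the "Karma" step) and extended level by
   level into larger patterns (the "Lego" step), pruning on the
   anti-monotonicity of vertical support (the fraction of patients
   containing an instance).
3. **Feature representation** — each frequent TIRP becomes one column whose
   value is the patient's mean instance duration (last interval end minus
   first interval start), 0 when absent.

Reference settings: alphabet 4 (SAX), epsilon 0, minimum vertical support
60%, patterns up to size 3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.base import BaseEstimator, TransformerMixin

from .cohort import CHANNELS, Cohort, PatientRecord
from .windowing import WindowGrid, WindowingError, paa, segment

REL_BEFORE = "before"
REL_OVERLAPS = "overlaps"
REL_CONTAINS = "contains"
_REL_CODES = {0: REL_BEFORE, 1: REL_OVERLAPS, 2: REL_CONTAINS}
_REL_IDS = {v: k for k, v in _REL_CODES.items()}
_REL_SHORT = {REL_BEFORE: "b", REL_OVERLAPS: "o", REL_CONTAINS: "c"}


class SymbolicError(ValueError):
    pass


@dataclass(frozen=True)
class SymbolInterval:
    """A maximal run of one symbol on one channel, ``[start, end)`` in hours."""

    channel: str
    symbol: int
    start: float
    end: float

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise SymbolicError(f"interval start {self.start} must precede end {self.end}")

    @property
    def sort_key(self):
        return (self.start, self.end, self.channel, self.symbol)


@dataclass(frozen=True)
class TIRP:
    """A time-interval-related pattern.

    ``symbols`` is the ordered tuple of ``(channel, symbol)`` labels;
    ``relations`` stores the upper-triangular relation half-matrix flattened
    column-wise (pairs (0,1), (0,2), (1,2), (0,3), ...), so extending the
    pattern appends one column.  ``support`` is the vertical support.
    """

    symbols: tuple[tuple[str, int], ...]
    relations: tuple[str, ...]
    support: float

    @property
    def size(self) -> int:
        return len(self.symbols)

    def relation(self, i: int, j: int) -> str:
        if not 0 <= i < j < self.size:
            raise SymbolicError(f"bad relation index ({i}, {j})")
        return self.relations[j * (j - 1) // 2 + i]

    def name(self) -> str:
        syms = [f"{ch}.s{s}" for ch, s in self.symbols]
        rels = "".join(_REL_SHORT[r] for r in self.relations)
        return "+".join(syms) + (f"[{rels}]" if rels else "")

    def to_json(self) -> dict:
        return {
            "symbols": [[ch, int(s)] for ch, s in self.symbols],
            "relations": list(self.relations),
            "support": self.support,
        }


# ---------------------------------------------------------------------------
# Discretization
# ---------------------------------------------------------------------------


def sax_breakpoints(alphabet: int) -> np.ndarray:
    """Standard-normal quantiles splitting the real line into ``alphabet``
    equal-probability bins."""
    if alphabet < 2:
        raise SymbolicError("alphabet must be >= 2")
    return norm.ppf(np.arange(1, alphabet) / alphabet)


def _merge_runs(symbols: np.ndarray, channel: str, grid: WindowGrid) -> list[SymbolInterval]:
    edges = grid.edges
    out: list[SymbolInterval] = []
    start = 0
    for i in range(1, len(symbols) + 1):
        if i == len(symbols) or symbols[i] != symbols[start]:
            out.append(
                SymbolInterval(channel, int(symbols[start]), float(edges[start]), float(edges[i]))
            )
            start = i
    return out


def sax_discretize(
    window_means: np.ndarray,
    channel: str,
    grid: WindowGrid,
    alphabet: int = 4,
    mu: float | None = None,
    sd: float | None = None,
) -> list[SymbolInterval]:
    """SAX-discretize one channel's window means into merged symbol intervals.

    ``mu``/``sd`` are the z-normalization statistics (supply training-cohort
    statistics to avoid leakage; default: the series' own moments).  A
    zero-spread series maps to the middle symbol.
    """
    x = np.asarray(window_means, dtype=float)
    mu = float(x.mean()) if mu is None else mu
    sd = float(x.std()) if sd is None else sd
    if sd <= 0:
        symbols = np.full(x.size, (alphabet + 1) // 2, dtype=int)
    else:
        z = (x - mu) / sd
        symbols = np.digitize(z, sax_breakpoints(alphabet)) + 1
    return _merge_runs(symbols, channel, grid)


def ewd_discretize(
    window_means: np.ndarray,
    channel: str,
    grid: WindowGrid,
    alphabet: int = 4,
    lo: float | None = None,
    hi: float | None = None,
) -> list[SymbolInterval]:
    """Equal-width discretization between ``lo`` and ``hi`` (training min/max
    by default); the top bin is closed, degenerate ranges map to the middle
    symbol."""
    if alphabet < 2:
        raise SymbolicError("alphabet must be >= 2")
    x = np.asarray(window_means, dtype=float)
    lo = float(x.min()) if lo is None else lo
    hi = float(x.max()) if hi is None else hi
    if hi <= lo:
        symbols = np.full(x.size, (alphabet + 1) // 2, dtype=int)
    else:
        inner = lo + (hi - lo) * np.arange(1, alphabet) / alphabet
        symbols = np.clip(np.digitize(x, inner) + 1, 1, alphabet)
    return _merge_runs(symbols, channel, grid)


# ---------------------------------------------------------------------------
# Relations and mining
# ---------------------------------------------------------------------------


def relation(i1: SymbolInterval, i2: SymbolInterval, epsilon: float = 0.0) -> str:
    """Abstract relation between two canonically ordered intervals.

    ``before`` if ``i1`` ends more than ``epsilon`` before ``i2`` starts;
    ``contains`` if ``i2`` lies within ``i1``; ``overlaps`` otherwise (this
    folds Allen's *meets*, *starts*, *finishes*, *equal* and *overlaps*).
    """
    if (i1.start, i1.end) > (i2.start, i2.end):
        raise SymbolicError("intervals must be passed in canonical order")
    if i1.end + epsilon < i2.start:
        return REL_BEFORE
    if i1.start <= i2.start and i2.end <= i1.end:
        return REL_CONTAINS
    return REL_OVERLAPS


def canonical_order(intervals: list[SymbolInterval]) -> list[SymbolInterval]:
    return sorted(intervals, key=lambda iv: iv.sort_key)


def _patient_arrays(intervals, vocab):
    ivs = canonical_order(intervals)
    start = np.array([iv.start for iv in ivs])
    end = np.array([iv.end for iv in ivs])
    sym = np.array([vocab.setdefault((iv.channel, iv.symbol), len(vocab)) for iv in ivs])
    return start, end, sym


def _rel_matrix(start: np.ndarray, end: np.ndarray, epsilon: float) -> np.ndarray:
    """Full pairwise relation code matrix (valid for i < j in canonical order)."""
    before = end[:, None] + epsilon < start[None, :]
    contains = (start[:, None] <= start[None, :]) & (end[None, :] <= end[:, None])
    return np.where(before, 0, np.where(contains, 2, 1)).astype(np.int8)


def mine_tirps(
    database: list[list[SymbolInterval]],
    min_support: float = 0.6,
    k_max: int = 3,
    epsilon: float = 0.0,
) -> list[TIRP]:
    """Mine all TIRPs of size 2..``k_max`` with vertical support >= threshold.

    Breadth-first discovery of size-2 patterns followed by level-wise
    extension, pruning infrequent patterns before extension (support is
    anti-monotone in pattern size, which is also asserted during mining).
    Returns patterns sorted by (size, -support, name).
    """
    if not 0 < min_support <= 1:
        raise SymbolicError("min_support must be in (0, 1]")
    n_patients = len(database)
    if n_patients == 0 or k_max < 2:
        return []

    vocab: dict[tuple[str, int], int] = {}
    patients = [_patient_arrays(ivs, vocab) for ivs in database]
    inv_vocab = {v: k for k, v in vocab.items()}

    def frequent(count: int) -> bool:
        return count / n_patients + 1e-12 >= min_support

    # Karma: all size-2 candidates by exhaustive pair enumeration.  Pair keys
    # (s1, s2, rel) are packed into integers for vectorized grouping.
    V = max(len(vocab), 1)
    pair_cache: list[tuple | None] = []
    uniq_per_patient = []
    for start, end, sym in patients:
        n = start.size
        if n < 2:
            pair_cache.append(None)
            continue
        ii, jj = np.triu_indices(n, 1)
        rel = _rel_matrix(start, end, epsilon)[ii, jj]
        keyid = (sym[ii].astype(np.int64) * V + sym[jj]) * 3 + rel
        pair_cache.append((ii, jj, keyid))
        uniq_per_patient.append(np.unique(keyid))

    results: list[TIRP] = []
    level: dict[tuple, float] = {}
    if uniq_per_patient:
        uniq, cnt = np.unique(np.concatenate(uniq_per_patient), return_counts=True)
        for kid, c in zip(uniq, cnt):
            if frequent(int(c)):
                q, r12 = divmod(int(kid), 3)
                s1, s2 = divmod(q, V)
                level[(s1, s2, r12)] = int(c) / n_patients
    support_of = dict(level)

    def to_tirp(key: tuple, support: float) -> TIRP:
        k = _key_size(key)
        syms = tuple(inv_vocab[key[i]] for i in range(k))
        rels = tuple(_REL_CODES[c] for c in key[k:])
        return TIRP(syms, rels, support)

    results.extend(to_tirp(k, s) for k, s in level.items())

    # Lego, level 2 -> 3: per patient, group the frequent pairs once and
    # enumerate every extension vectorized; each patient contributes each
    # candidate triple key at most once, so a global unique-with-counts
    # yields vertical supports directly.
    size = 2
    if k_max >= 3 and level:
        freq_ids = np.sort(
            np.array([(k[0] * V + k[1]) * 3 + k[2] for k in level], dtype=np.int64)
        )
        counter: dict[int, int] = {}
        chunk: list[np.ndarray] = []

        def _flush() -> None:
            if not chunk:
                return
            u, c = np.unique(np.concatenate(chunk), return_counts=True)
            for code, cc in zip(u.tolist(), c.tolist()):
                counter[code] = counter.get(code, 0) + cc
            chunk.clear()

        for p, (start, end, sym) in enumerate(patients):
            pc = pair_cache[p]
            n = start.size
            if pc is None or n < 3:
                continue
            ii, jj, keyid = pc
            pos = np.searchsorted(freq_ids, keyid)
            pos[pos == freq_ids.size] = 0
            mask = freq_ids[pos] == keyid
            tails = n - 1 - jj
            mask &= tails > 0
            if not mask.any():
                continue
            ii_f, jj_f, kid_f, tails_f = ii[mask], jj[mask], keyid[mask], tails[mask]
            relm = _rel_matrix(start, end, epsilon)
            row_idx = np.repeat(np.arange(ii_f.size), tails_f)
            l_all = np.concatenate([np.arange(j + 1, n) for j in jj_f])
            code = (
                (kid_f[row_idx] * V + sym[l_all]) * 3 + relm[ii_f[row_idx], l_all]
            ) * 3 + relm[jj_f[row_idx], l_all]
            chunk.append(np.unique(code))
            if len(chunk) >= 64:
                _flush()
        _flush()

        level = {}
        for code, c in counter.items():
            rest, r23 = divmod(code, 3)
            rest, r13 = divmod(rest, 3)
            kid, s3 = divmod(rest, V)
            q, r12 = divmod(kid, 3)
            s1, s2 = divmod(q, V)
            sup = c / n_patients
            assert (
                sup <= support_of.get((s1, s2, r12), 1.0) + 1e-12
            ), "anti-monotonicity violated"
            if frequent(c):
                level[(s1, s2, s3, r12, r13, r23)] = sup
        support_of.update(level)
        results.extend(to_tirp(k, s) for k, s in level.items())
        size = 3

    # deeper levels: instance-based extension (practical at toy scale only)
    while size < k_max and level:
        nxt_counts: dict[tuple, set[int]] = {}
        for p, (start, end, sym) in enumerate(patients):
            n = start.size
            if n <= size:
                continue
            relm = _rel_matrix(start, end, epsilon)
            for key in level:
                inst = _match_instances(patients[p], key, epsilon, None, relm)
                if inst.size == 0:
                    continue
                parent_syms = key[:size]
                parent_rels = key[size:]
                lasts = inst[:, -1]
                tails = n - 1 - lasts
                keep = tails > 0
                if not keep.any():
                    continue
                inst = inst[keep]
                row_idx = np.repeat(np.arange(inst.shape[0]), tails[keep])
                l_all = np.concatenate([np.arange(last + 1, n) for last in inst[:, -1]])
                newrels = relm[inst[row_idx].T, l_all]  # (size, T)
                varying = np.unique(
                    np.concatenate([sym[l_all][None, :], newrels], axis=0).T, axis=0
                )
                for row in varying:
                    newkey = (
                        parent_syms
                        + (int(row[0]),)
                        + parent_rels
                        + tuple(int(x) for x in row[1:])
                    )
                    nxt_counts.setdefault(newkey, set()).add(p)
        level = {}
        for key, who in nxt_counts.items():
            sup = len(who) / n_patients
            parent = key[:size] + key[size + 1 : size + 1 + size * (size - 1) // 2]
            assert sup <= support_of.get(parent, 1.0) + 1e-12, "anti-monotonicity violated"
            if frequent(len(who)):
                level[key] = sup
                support_of[key] = sup
        results.extend(to_tirp(k, s) for k, s in level.items())
        size += 1

    results.sort(key=lambda t: (t.size, -t.support, t.name()))
    return results


def _key_size(key: tuple) -> int:
    # key = (s_1..s_k, r_1..r_{k(k-1)/2}); solve len = k(k+1)/2 for k
    total = len(key)
    k = int(round((np.sqrt(8 * total + 1) - 1) / 2))
    assert k + k * (k - 1) // 2 == total
    return k


def _match_instances(patient, key, epsilon, pairs=None, relm=None) -> np.ndarray:
    """All index tuples in one patient matching a TIRP key.

    Returns an ``(n_instances, k)`` integer array (possibly empty).
    """
    start, end, sym = patient
    k = _key_size(key)
    syms = key[:k]
    rels = key[k:]
    n = start.size
    if n < k:
        return np.empty((0, k), dtype=int)
    if relm is None:
        relm = _rel_matrix(start, end, epsilon)
    if k == 2:
        ii, jj = np.triu_indices(n, 1)
        mask = (sym[ii] == syms[0]) & (sym[jj] == syms[1]) & (relm[ii, jj] == rels[0])
        return np.stack([ii[mask], jj[mask]], axis=1)
    partial = np.flatnonzero(sym == syms[0])[:, None]
    for pos in range(1, k):
        if partial.size == 0:
            return np.empty((0, k), dtype=int)
        new_rows = []
        col0 = pos * (pos - 1) // 2
        for row in partial:
            cand = np.arange(row[-1] + 1, n)
            cand = cand[sym[cand] == syms[pos]]
            for x in range(pos):
                if cand.size == 0:
                    break
                cand = cand[relm[row[x], cand] == rels[col0 + x]]
            for l in cand:
                new_rows.append(np.append(row, l))
        partial = (
            np.asarray(new_rows, dtype=int)
            if new_rows
            else np.empty((0, pos + 1), dtype=int)
        )
    return partial


def find_instances(
    intervals: list[SymbolInterval], tirp: TIRP, epsilon: float = 0.0
) -> list[list[SymbolInterval]]:
    """All instances of a TIRP in one patient's interval list."""
    vocab: dict[tuple[str, int], int] = {}
    patient = _patient_arrays(intervals, vocab)
    try:
        key = tuple(vocab[s] for s in tirp.symbols) + tuple(_REL_IDS[r] for r in tirp.relations)
    except KeyError:
        return []
    ivs = canonical_order(intervals)
    return [[ivs[i] for i in row] for row in _match_instances(patient, key, epsilon)]


def tirp_matrix(
    database: list[list[SymbolInterval]],
    frequent: list[TIRP],
    epsilon: float = 0.0,
    index=None,
) -> pd.DataFrame:
    """Mean-duration feature matrix: one row per patient, one column per TIRP.

    A patient's value for a TIRP is the mean, over all instances, of the span
    from the first interval's start to the last interval's end; 0 if absent.
    """
    if not frequent:
        raise SymbolicError("frequent TIRP set is empty")
    cols = [t.name() for t in frequent]
    out = np.zeros((len(database), len(frequent)))
    for p, intervals in enumerate(database):
        vocab: dict[tuple[str, int], int] = {}
        patient = _patient_arrays(intervals, vocab)
        start, end, _ = patient
        n = start.size
        relm = _rel_matrix(start, end, epsilon) if n else None
        for j, tirp in enumerate(frequent):
            try:
                key = tuple(vocab[s] for s in tirp.symbols) + tuple(
                    _REL_IDS[r] for r in tirp.relations
                )
            except KeyError:
                continue
            inst = _match_instances(patient, key, epsilon, relm=relm)
            if inst.size:
                out[p, j] = float(np.mean(end[inst[:, -1]] - start[inst[:, 0]]))
    return pd.DataFrame(out, columns=cols, index=index)


# ---------------------------------------------------------------------------
# Transformer
# ---------------------------------------------------------------------------


class TIRPFeaturizer(BaseEstimator, TransformerMixin):
    """SAX/EWD abstraction + TIRP mining as a scikit-learn transformer.

    ``fit`` learns the discretization statistics (z-normalization moments
    for SAX, min/max for EWD) and the frequent TIRP set from the training
    records only; ``transform`` discretizes with the stored statistics and
    emits the mean-duration matrix for the learned patterns.
    """

    def __init__(
        self,
        alphabet: int = 4,
        discretizer: str = "sax",
        min_support: float = 0.6,
        k_max: int = 3,
        epsilon: float = 0.0,
        window_hours: float = 2.0,
        horizon: float = 48.0,
        channels=None,
        imputation: str = "carry",
    ):
        self.alphabet = alphabet
        self.discretizer = discretizer
        self.min_support = min_support
        self.k_max = k_max
        self.epsilon = epsilon
        self.window_hours = window_hours
        self.horizon = horizon
        self.channels = channels
        self.imputation = imputation

    def _grid(self) -> WindowGrid:
        return WindowGrid(self.horizon, self.window_hours)

    def _window_means(self, rec: PatientRecord, ch: str, grid: WindowGrid) -> np.ndarray | None:
        series = rec.channels.get(ch)
        if series is None or len(series) == 0:
            return None
        try:
            return paa(segment(series.truncated(grid.horizon), grid), self.imputation).values
        except WindowingError:
            return None

    def fit(self, X, y=None):
        if self.discretizer not in ("sax", "ewd"):
            raise SymbolicError(f"unknown discretizer {self.discretizer!r}")
        if self.alphabet < 2:
            raise SymbolicError("alphabet must be >= 2")
        records = X.records if isinstance(X, Cohort) else list(X)
        grid = self._grid()
        self.channels_ = list(self.channels) if self.channels is not None else list(CHANNELS)
        means = {ch: [] for ch in self.channels_}
        per_patient: list[dict[str, np.ndarray]] = []
        for rec in records:
            d = {}
            for ch in self.channels_:
                wm = self._window_means(rec, ch, grid)
                if wm is not None:
                    d[ch] = wm
                    means[ch].append(wm)
            per_patient.append(d)
        self.stats_ = {}
        for ch in self.channels_:
            if means[ch]:
                all_m = np.concatenate(means[ch])
                self.stats_[ch] = {
                    "mu": float(all_m.mean()),
                    "sd": float(all_m.std()),
                    "lo": float(all_m.min()),
                    "hi": float(all_m.max()),
                }
            else:
                self.stats_[ch] = {"mu": 0.0, "sd": 0.0, "lo": 0.0, "hi": 0.0}
        database = [self._discretize_patient(d, grid) for d in per_patient]
        self.tirps_ = mine_tirps(database, self.min_support, self.k_max, self.epsilon)
        self.feature_names_ = [t.name() for t in self.tirps_] or ["no_frequent_tirp"]
        self._prepare_matcher()
        return self

    def _prepare_matcher(self) -> None:
        """Pack the mined size-2/3 patterns into integer codes so transform
        can aggregate instance durations with vectorized lookups."""
        vocab: dict[tuple[str, int], int] = {}
        for t in self.tirps_:
            for s in t.symbols:
                vocab.setdefault(s, len(vocab))
        self._vocab_ = vocab
        V = len(vocab) + 1  # one spare id for symbols unseen at fit time
        self._V_ = V
        codes2, cols2, codes3, cols3 = [], [], [], []
        self._fast_ok_ = True
        for j, t in enumerate(self.tirps_):
            ids = [vocab[s] for s in t.symbols]
            rels = [_REL_IDS[r] for r in t.relations]
            if t.size == 2:
                codes2.append((ids[0] * V + ids[1]) * 3 + rels[0])
                cols2.append(j)
            elif t.size == 3:
                c2 = (ids[0] * V + ids[1]) * 3 + rels[0]
                codes3.append(((c2 * V + ids[2]) * 3 + rels[1]) * 3 + rels[2])
                cols3.append(j)
            else:
                self._fast_ok_ = False
        o2 = np.argsort(codes2)
        self._codes2_ = np.asarray(codes2, dtype=np.int64)[o2]
        self._cols2_ = np.asarray(cols2, dtype=int)[o2]
        o3 = np.argsort(codes3)
        self._codes3_ = np.asarray(codes3, dtype=np.int64)[o3]
        self._cols3_ = np.asarray(cols3, dtype=int)[o3]
        # parents of the mined triples: only these pairs need extending
        self._parent2_ = np.unique(self._codes3_ // (V * 9))

    def _fast_row(self, intervals: list[SymbolInterval]) -> np.ndarray:
        """Mean instance duration per mined TIRP for one patient."""
        out = np.zeros(len(self.tirps_))
        ivs = canonical_order(intervals)
        n = len(ivs)
        if n < 2:
            return out
        V = self._V_
        unknown = len(self._vocab_)
        start = np.array([iv.start for iv in ivs])
        end = np.array([iv.end for iv in ivs])
        sym = np.array(
            [self._vocab_.get((iv.channel, iv.symbol), unknown) for iv in ivs],
            dtype=np.int64,
        )
        relm = _rel_matrix(start, end, self.epsilon)
        ii, jj = np.triu_indices(n, 1)
        code2 = (sym[ii] * V + sym[jj]) * 3 + relm[ii, jj]

        def _accumulate(codes_sorted, cols, rowcodes, durations):
            if codes_sorted.size == 0 or rowcodes.size == 0:
                return
            pos = np.searchsorted(codes_sorted, rowcodes)
            pos[pos == codes_sorted.size] = 0
            ok = codes_sorted[pos] == rowcodes
            if not ok.any():
                return
            sums = np.zeros(codes_sorted.size)
            cnts = np.zeros(codes_sorted.size)
            np.add.at(sums, pos[ok], durations[ok])
            np.add.at(cnts, pos[ok], 1.0)
            hit = cnts > 0
            out[cols[hit]] = sums[hit] / cnts[hit]

        _accumulate(self._codes2_, self._cols2_, code2, end[jj] - start[ii])

        if self._codes3_.size and n >= 3:
            pos = np.searchsorted(self._parent2_, code2)
            pos[pos == self._parent2_.size] = 0
            mask = (self._parent2_[pos] == code2) & (n - 1 - jj > 0)
            if mask.any():
                ii_f, jj_f, c2_f = ii[mask], jj[mask], code2[mask]
                tails = n - 1 - jj_f
                row_idx = np.repeat(np.arange(ii_f.size), tails)
                l_all = np.concatenate([np.arange(j + 1, n) for j in jj_f])
                code3 = (
                    (c2_f[row_idx] * V + sym[l_all]) * 3 + relm[ii_f[row_idx], l_all]
                ) * 3 + relm[jj_f[row_idx], l_all]
                _accumulate(
                    self._codes3_, self._cols3_, code3, end[l_all] - start[ii_f[row_idx]]
                )
        return out

    def _discretize_patient(self, wm_by_channel: dict, grid: WindowGrid) -> list[SymbolInterval]:
        intervals: list[SymbolInterval] = []
        for ch, wm in wm_by_channel.items():
            s = self.stats_[ch]
            if self.discretizer == "sax":
                intervals.extend(
                    sax_discretize(wm, ch, grid, self.alphabet, mu=s["mu"], sd=s["sd"])
                )
            else:
                intervals.extend(
                    ewd_discretize(wm, ch, grid, self.alphabet, lo=s["lo"], hi=s["hi"])
                )
        return canonical_order(intervals)

    def transform(self, X) -> pd.DataFrame:
        if not hasattr(self, "tirps_"):
            raise SymbolicError("TIRPFeaturizer is not fitted")
        records = X.records if isinstance(X, Cohort) else list(X)
        grid = self._grid()
        database = []
        for rec in records:
            d = {}
            for ch in self.channels_:
                wm = self._window_means(rec, ch, grid)
                if wm is not None:
                    d[ch] = wm
            database.append(self._discretize_patient(d, grid))
        if not self.tirps_:
            # no frequent pattern survived mining: emit a constant column so a
            # downstream classifier degrades to the majority class
            return pd.DataFrame(
                np.zeros((len(records), 1)),
                columns=["no_frequent_tirp"],
                index=[r.patient_id for r in records],
            )
        ids = [r.patient_id for r in records]
        if self._fast_ok_:
            rows = np.stack([self._fast_row(ivs) for ivs in database])
            return pd.DataFrame(rows, columns=self.feature_names_, index=ids)
        return tirp_matrix(database, self.tirps_, self.epsilon, index=ids)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.feature_names_, dtype=object)

    def tirps_to_json(self) -> list[dict]:
        return [t.to_json() for t in self.tirps_]


__all__ = [
    "REL_BEFORE",
    "REL_OVERLAPS",
    "REL_CONTAINS",
    "SymbolInterval",
    "TIRP",
    "SymbolicError",
    "sax_breakpoints",
    "sax_discretize",
    "ewd_discretize",
    "relation",
    "canonical_order",
    "mine_tirps",
    "find_instances",
    "tirp_matrix",
    "TIRPFeaturizer",
]
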