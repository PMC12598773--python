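"""Read recruitment, alignment to reference columns, and phylogenetic placement.

The pipeline stage chain is:

1. **recruit**: translate each 150 bp mate in all six frames and score an
   ungapped local alignment (BLOSUM62, exact-word seeded, like a
   translated BLAST search) against per-clade representative reference
   sequences; the best hit anchors the mate's residues onto reference
   alignment columns.
2. **merge**: the two mates of a pair are combined into one column->residue
   map (non-overlapping mates simply union; conflicts go to the
   higher-scoring mate).
3. **place**: the merged query is attached by a pendant branch at the
   midpoint of every reference edge in turn; the pendant length is
   optimized and the edge with the highest log-likelihood wins (one
   placement per query).  The likelihood uses an equal-rates amino-acid
   model via Felsenstein pruning, with per-edge partials precomputed once
   per reference package.
4. **filter/assign**: placements with pendant length > 2 substitutions/site
   are discarded (poor fits); the rest inherit their edge's taxonomic
   label and are counted at every rank of that label.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices
from Bio.Data.CodonTable import standard_dna_table

from .refdata import EdgeLabeling, ReferencePackage
from .substitution import AMINO_ACIDS, N_STATES, _LAM

#: default pendant-length cutoff, substitutions/site (reads fitting worse
#: than this are considered spurious placements)
PENDANT_THRESHOLD = 2.0

#: default minimum recruitment score (raw BLOSUM62 ungapped segment score);
#: calibrated by simulation so that i.i.d.-random 150-mers pass < 1% of the
#: time while intact marker reads score far above it
MIN_SCORE = 45.0

_BAD = 20          # translation artifacts: stop codons, X
_PAD = 21          # separator between concatenated reference sequences
_FRAMES = (1, 2, 3, -1, -2, -3)


def _build_substitution_matrix() -> np.ndarray:
    blosum = substitution_matrices.load("BLOSUM62")
    m = np.full((22, 22), -1e5, dtype=np.float32)
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            m[i, j] = blosum[a][b]
    m[_BAD, :20] = m[:20, _BAD] = -4.0
    m[_BAD, _BAD] = -4.0
    return m


_SUB = _build_substitution_matrix()
_AA_CODE = np.full(128, _BAD, dtype=np.int64)
for _i, _a in enumerate(AMINO_ACIDS):
    _AA_CODE[ord(_a)] = _i


def _encode_query(aa: str) -> np.ndarray:
    return _AA_CODE[np.frombuffer(aa.encode("ascii", "replace"), dtype=np.uint8) & 0x7F]


# vectorized translation: codon code (base-4) -> aa state code
_NT_CODE = np.full(128, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _NT_CODE[ord(_b)] = _i
    _NT_CODE[ord(_b.lower())] = _i
_CODON_AA = np.full(64, _BAD, dtype=np.int64)
for _codon, _aa in standard_dna_table.forward_table.items():
    _idx = _NT_CODE[ord(_codon[0])] * 16 + _NT_CODE[ord(_codon[1])] * 4 + \
        _NT_CODE[ord(_codon[2])]
    _CODON_AA[_idx] = _AA_CODE[ord(_aa)]


def _translate_codes(nt: np.ndarray) -> np.ndarray:
    """Translate nucleotide codes (0..3) in frame 0; length // 3 residues."""
    k = len(nt) // 3
    c = nt[:3 * k].reshape(k, 3)
    return _CODON_AA[c[:, 0] * 16 + c[:, 1] * 4 + c[:, 2]]


@dataclass
class AlignedQuery:
    """A recruited read (or merged pair) mapped onto reference columns."""

    query_id: str
    gene: str
    columns: np.ndarray        # alignment columns, strictly increasing
    residues: np.ndarray       # aa state codes 0..19, parallel to columns
    score: float               # recruitment score (bits-like)
    mates_used: tuple[int, ...] = (1,)
    frames: dict[int, int] = field(default_factory=dict)  # mate -> frame

    def __post_init__(self) -> None:
        if len(self.columns) != len(self.residues):
            raise ValueError("columns/residues length mismatch")
        if len(self.columns) and np.any(np.diff(self.columns) <= 0):
            raise ValueError("columns must be strictly increasing")


@dataclass
class Placement:
    """Single best placement of one query on the reference tree."""

    query_id: str
    gene: str
    edge_id: int
    pendant_length: float      # substitutions/site
    log_likelihood: float
    clade: tuple[str, ...]     # assigned clade path = edge label
    sample_id: str | None = None


# ---------------------------------------------------------------------------
# recruitment


class Recruiter:
    """Seeded ungapped translated search against one or more packages.

    One representative leaf per distinct taxonomy path (configurable) is
    indexed by exact amino-acid words of length ``word_size``; a query
    frame's words vote for (reference, diagonal) candidates, and the top
    candidates are scored by the maximum-sum ungapped segment under
    BLOSUM62.  The best segment anchors query residues to the reference
    alignment columns of the matched reference positions.
    """

    def __init__(self, packages, representatives_per_clade: int = 1,
                 word_size: int = 5, max_candidates: int = 8):
        if isinstance(packages, ReferencePackage):
            packages = [packages]
        self.word_size = word_size
        self.max_candidates = max_candidates
        self.refs: list[dict] = []       # gene, label, codes, columns
        for pkg in packages:
            by_path: dict[tuple, list[str]] = {}
            for node in pkg.tree.leaves:
                label = pkg.tree.leaf_labels[node]
                by_path.setdefault(pkg.taxonomy.paths[label], []).append(label)
            for path in sorted(by_path):
                for label in sorted(by_path[path])[:representatives_per_clade]:
                    row = pkg.alignment.sequences[label]
                    codes, cols = [], []
                    for col, ch in enumerate(row):
                        c = _AA_CODE[ord(ch) & 0x7F] if ch.isalpha() else _BAD
                        if ch in "-." or c == _BAD:
                            continue
                        codes.append(c)
                        cols.append(col)
                    self.refs.append(dict(
                        gene=pkg.gene, label=label,
                        codes=np.array(codes, dtype=np.int64),
                        columns=np.array(cols, dtype=np.int64)))
        # word index: word value -> array rows (ref_idx, ref_pos)
        w = word_size
        entries = []
        for ridx, ref in enumerate(self.refs):
            codes = ref["codes"]
            if len(codes) < w:
                continue
            words = np.zeros(len(codes) - w + 1, dtype=np.int64)
            for k in range(w):
                words = words * 21 + codes[k:len(codes) - w + 1 + k]
            for pos, word in enumerate(words):
                entries.append((word, ridx, pos))
        entries.sort()
        self._words = np.array([e[0] for e in entries], dtype=np.int64)
        self._word_refs = np.array([(e[1], e[2]) for e in entries],
                                   dtype=np.int64).reshape(-1, 2)

    # -- per-mate search

    def _frame_translations(self, seq: str) -> list[tuple[int, np.ndarray]]:
        nt = _NT_CODE[np.frombuffer(seq.encode("ascii", "replace"),
                                    dtype=np.uint8) & 0x7F]
        if np.any(nt < 0):
            return []
        rc = 3 - nt[::-1]
        return [(frame, _translate_codes((nt if frame > 0 else rc)[abs(frame) - 1:]))
                for frame in _FRAMES]

    def recruit_mate(self, seq: str, min_score: float = MIN_SCORE):
        """Best hit for one mate, or None.

        Returns a dict with gene, label, score, frame, columns, residues.
        """
        if not seq:
            return None
        w = self.word_size
        frames = self._frame_translations(seq)
        if not frames:
            return None
        keys, counts_list = [], []
        for fidx, (frame, q) in enumerate(frames):
            if len(q) < w:
                continue
            words = np.zeros(len(q) - w + 1, dtype=np.int64)
            for k in range(w):
                words = words * 21 + q[k:len(q) - w + 1 + k]
            lo = np.searchsorted(self._words, words, side="left")
            hi = np.searchsorted(self._words, words, side="right")
            nhit = hi - lo
            total = int(nhit.sum())
            if total == 0:
                continue
            qpos = np.repeat(np.arange(len(words)), nhit)
            rows = np.concatenate([np.arange(a, b) for a, b in zip(lo, hi)
                                   if b > a])
            ridx = self._word_refs[rows, 0]
            shift = qpos - self._word_refs[rows, 1]
            # pack (frame, ref, shift) into one int for fast unique-counting
            packed = (fidx * len(self.refs) + ridx) * 4096 + (shift + 2048)
            uniq, cnt = np.unique(packed, return_counts=True)
            keys.append(uniq)
            counts_list.append(cnt)
        if not keys:
            return None
        allk = np.concatenate(keys)
        allc = np.concatenate(counts_list)
        order = np.argsort(-allc, kind="stable")[:self.max_candidates]
        top = []
        for key in allk[order]:
            key = int(key)
            shift = key % 4096 - 2048
            fr = key // 4096
            top.append((fr // len(self.refs), fr % len(self.refs), shift))
        best = None
        for fidx, ridx, shift in top:
            frame, q = frames[fidx]
            ref = self.refs[ridx]
            codes = ref["codes"]
            i0 = max(0, shift)
            i1 = min(len(q), len(codes) + shift)
            if i1 - i0 < w:
                continue
            scores = _SUB[q[i0:i1], codes[i0 - shift:i1 - shift]].astype(np.float64)
            # max-sum contiguous segment via cumulative sums
            c = np.concatenate([[0.0], np.cumsum(scores)])
            runmin = np.minimum.accumulate(c[:-1])
            gains = c[1:] - runmin
            jend = int(np.argmax(gains))           # segment ends at jend (incl)
            score = float(gains[jend])
            jstart = int(np.argmin(c[:jend + 1]))  # segment starts at jstart
            key = (score, -_FRAMES.index(frame), -ridx)
            if best is None or key > best[0]:
                best = (key, fidx, ridx, shift, i0 + jstart, i0 + jend + 1)
        if best is None:
            return None
        (score, _, _), fidx, ridx, shift, qs, qe = best
        if score < min_score:
            return None
        frame, q = frames[fidx]
        ref = self.refs[ridx]
        qres = q[qs:qe]
        cols = ref["columns"][qs - shift:qe - shift]
        keep = qres != _BAD
        return dict(gene=ref["gene"], label=ref["label"], score=score,
                    frame=frame, columns=cols[keep], residues=qres[keep])

    def recruit_pair(self, query_id: str, mate1: str, mate2: str | None,
                     min_score: float = MIN_SCORE):
        """Recruit both mates and merge; returns (AlignedQuery|None, reason)."""
        hits = []
        for k, seq in enumerate((mate1, mate2), start=1):
            if seq is None:
                continue
            hit = self.recruit_mate(seq, min_score)
            if hit is not None:
                hits.append((k, hit))
        if not hits:
            return None, "no_hit"
        genes = {h["gene"] for _, h in hits}
        if len(genes) > 1:
            return None, "gene_conflict"
        queries = []
        for k, h in hits:
            if len(h["columns"]) == 0:
                continue
            queries.append(AlignedQuery(
                query_id=query_id, gene=h["gene"], columns=h["columns"],
                residues=h["residues"], score=h["score"],
                mates_used=(k,), frames={k: h["frame"]}))
        if not queries:
            return None, "no_columns"
        merged = queries[0] if len(queries) == 1 else merge_mates(*queries[:2])
        if len(merged.columns) < 10:
            return None, "too_few_columns"
        return merged, "ok"


def recruit_and_translate(read, package: ReferencePackage,
                          min_score: float = MIN_SCORE):
    """Convenience wrapper: recruit one read pair against one package.

    ``read`` is anything with ``read_id``, ``mate1``, ``mate2`` attributes
    (e.g. a ``SyntheticRead``).  Returns (AlignedQuery | None, reason).
    For batch work build one :class:`Recruiter` and reuse it.
    """
    return Recruiter([package]).recruit_pair(read.read_id, read.mate1,
                                             read.mate2, min_score)


def merge_mates(q1: AlignedQuery, q2: AlignedQuery) -> AlignedQuery:
    """Combine two mates into one column->residue map.

    Disjoint columns union; on conflict the residue from the mate with the
    higher recruitment score wins (ties go to mate 1).
    """
    if len(q1.columns) == 0 or len(q2.columns) == 0:
        raise ValueError("cannot merge an empty aligned query")
    if q1.gene != q2.gene:
        raise ValueError("cannot merge mates recruited to different genes")
    # order so that the winner is written last
    loser, winner = (q2, q1) if q1.score >= q2.score else (q1, q2)
    combined: dict[int, int] = dict(zip(loser.columns.tolist(),
                                        loser.residues.tolist()))
    combined.update(zip(winner.columns.tolist(), winner.residues.tolist()))
    cols = np.array(sorted(combined), dtype=np.int64)
    res = np.array([combined[c] for c in cols], dtype=np.int64)
    return AlignedQuery(
        query_id=q1.query_id, gene=q1.gene, columns=cols, residues=res,
        score=max(q1.score, q2.score),
        mates_used=tuple(sorted(set(q1.mates_used) | set(q2.mates_used))),
        frames={**q1.frames, **q2.frames})


# ---------------------------------------------------------------------------
# placement


PENDANT_BOUNDS = (1e-8, 10.0)


def _trans(arr: np.ndarray, t: float) -> np.ndarray:
    """Apply the equal-rates transition operator along a branch of length t.

    (closed form: P(t) x = p_diff * sum(x) + (p_same - p_diff) * x)
    """
    u = np.exp(-_LAM * t)
    pd_ = (1.0 - u) / N_STATES
    return pd_ * arr.sum(axis=-1, keepdims=True) + u * arr


class PlacementEngine:
    """Per-edge likelihood machinery for one reference package.

    For every edge the partial likelihoods of the two tree halves, seen
    from the edge midpoint, are precomputed for every alignment column.
    Placing a query then reduces to a closed-form one-dimensional
    likelihood in the pendant length, optimized by a vectorized
    golden-section search over all edges at once.
    """

    def __init__(self, package: ReferencePackage):
        self.package = package
        tree = package.tree
        C = package.alignment.n_columns
        E = tree.n_edges
        leaf_mat, rows = package.encoded_leaf_matrix()

        # down (inner) partials, post-order
        L = np.zeros((tree.n_nodes, C, N_STATES))
        logL = np.zeros((tree.n_nodes, C))
        M = np.zeros((E, C, N_STATES))   # partial transported across edge e
        for node in range(tree.n_nodes):
            if tree.is_leaf(node):
                codes = leaf_mat[rows[node]]
                part = np.zeros((C, N_STATES))
                part[codes < 0] = 1.0                      # gap = missing
                ok = codes >= 0
                part[np.nonzero(ok)[0], codes[ok]] = 1.0
                L[node] = part
            else:
                part = np.ones((C, N_STATES))
                for ch in tree.children[node]:
                    part = part * M[ch]
                    logL[node] += logL[ch]
                scale = part.max(axis=1)
                scale[scale == 0] = 1.0
                part /= scale[:, None]
                logL[node] += np.log(scale)
                L[node] = part
            if node != tree.root:
                M[node] = _trans(L[node], tree.branch_length[node])

        # up (outer) partials and per-edge midpoint views, pre-order
        W = np.zeros((E, C, N_STATES))   # pi * down * up at the midpoint
        logS = np.zeros((E, C))
        O = np.zeros((tree.n_nodes, C, N_STATES))
        logO = np.zeros((tree.n_nodes, C))
        O[tree.root] = 1.0
        for node in range(tree.n_nodes - 1, -1, -1):
            ch = tree.children[node]
            if not ch:
                continue
            # prefix/suffix products of sibling partials (avoids division)
            k = len(ch)
            pre = [None] * (k + 1)
            pre[0] = np.ones((C, N_STATES))
            for i in range(k):
                pre[i + 1] = pre[i] * M[ch[i]]
            suf = [None] * (k + 1)
            suf[k] = np.ones((C, N_STATES))
            for i in range(k - 1, -1, -1):
                suf[i] = suf[i + 1] * M[ch[i]]
            chlog_total = np.zeros(C)
            for c in ch:
                chlog_total = chlog_total + logL[c]
            for i, c in enumerate(ch):
                X = O[node] * pre[i] * suf[i + 1]
                logX = logO[node] + chlog_total - logL[c]
                scale = X.max(axis=1)
                scale[scale == 0] = 1.0
                X /= scale[:, None]
                logX = logX + np.log(scale)
                half = tree.branch_length[c] / 2.0
                U = _trans(X, half)
                D = _trans(L[c], half)
                w = D * U / N_STATES
                wmax = w.max(axis=1)
                wmax[wmax == 0] = 1.0
                W[c] = w / wmax[:, None]
                logS[c] = logL[c] + logX + np.log(wmax)
                O[c] = _trans(X, tree.branch_length[c])
                logO[c] = logX

        self._W = W
        self._A = W.sum(axis=2)
        self._logS = logS
        self.n_edges = E

    def _edge_loglik(self, coef0, coef1, base, v):
        """Log-likelihood per edge at per-edge pendant lengths v."""
        u = np.exp(-_LAM * np.asarray(v)[:, None])
        vals = coef0 + coef1 * u
        return np.log(np.maximum(vals, 1e-300)).sum(axis=1) + base

    def place(self, query: AlignedQuery,
              sample_id: str | None = None) -> Placement | None:
        """Maximum-likelihood single placement of one aligned query."""
        cols = query.columns
        if len(cols) == 0:
            return None
        res = query.residues
        A = self._A[:, cols]                       # (E, nq)
        B = self._W[:, cols, res]
        base = self._logS[:, cols].sum(axis=1)     # (E,)
        coef0 = A / N_STATES
        coef1 = B - coef0
        if np.all(coef0 + coef1 <= 0):
            return None

        lo, hi = PENDANT_BOUNDS
        E = self.n_edges
        # per-column likelihood is a + b*u with u = exp(-lam*v); the summed
        # log-likelihood is concave in u, so its derivative
        # g(u) = sum b/(a + b*u) is monotone decreasing: root-find g by
        # safeguarded Newton/bisection, vectorized over edges.
        u_lo = float(np.exp(-_LAM * hi))
        u_hi = float(np.exp(-_LAM * lo))

        def gprime(u):
            den = coef0 + coef1 * u[:, None]
            ok = den > 0
            den = np.where(ok, den, 1.0)
            ratio = np.where(ok, coef1 / den, 0.0)
            return ratio.sum(axis=1), (ratio * ratio).sum(axis=1)

        g_hi, _ = gprime(np.full(E, u_hi))
        g_lo, _ = gprime(np.full(E, u_lo))
        lo_b = np.full(E, u_lo)
        hi_b = np.full(E, u_hi)
        u = 0.5 * (lo_b + hi_b)
        interior = (g_hi < 0) & (g_lo > 0)
        for _ in range(28):
            g, gsq = gprime(u)
            lo_b = np.where(g > 0, u, lo_b)
            hi_b = np.where(g <= 0, u, hi_b)
            step = np.where(gsq > 0, g / np.maximum(gsq, 1e-300), 0.0)
            cand = u + step                      # Newton (g' = -sum r^2)
            mid = 0.5 * (lo_b + hi_b)
            u = np.where((cand > lo_b) & (cand < hi_b), cand, mid)
        u = np.where(interior, u, np.where(g_hi >= 0, u_hi, u_lo))
        v = -np.log(u) / _LAM
        v = np.clip(v, lo, hi)
        ll = self._edge_loglik(coef0, coef1, base, v)
        if not np.any(np.isfinite(ll)):
            return None
        best = np.nanmax(ll)
        edge = int(np.nonzero(ll >= best - 1e-9)[0][0])  # tie -> lowest edge id
        return Placement(query_id=query.query_id, gene=query.gene,
                         edge_id=edge, pendant_length=float(v[edge]),
                         log_likelihood=float(ll[edge]),
                         clade=self.package.labeling[edge],
                         sample_id=sample_id)


def place_query(query: AlignedQuery, package: ReferencePackage,
                sample_id: str | None = None) -> Placement | None:
    """One-shot placement (builds the engine; reuse PlacementEngine for batches)."""
    return PlacementEngine(package).place(query, sample_id)


def filter_pendant(placements, threshold: float = PENDANT_THRESHOLD):
    """Split placements into (kept, removed) by pendant length.

    A placement is kept iff its pendant length is <= threshold (strictly
    greater pendants are removed).
    """
    if threshold <= 0:
        raise ValueError("pendant threshold must be > 0")
    kept = [p for p in placements if p.pendant_length <= threshold]
    removed = [p for p in placements if p.pendant_length > threshold]
    return kept, removed


def assign_and_count(placements, labeling: EdgeLabeling) -> pd.Series:
    """Count placements at every taxonomic rank of their edge label.

    A read placed on an ``Ia`` edge counts toward ``Ia`` (and its
    ancestors) but toward no sub-ecotype.  Returns a Series indexed by
    semicolon-joined clade paths.
    """
    counts: Counter = Counter()
    for p in placements:
        if p.edge_id not in labeling:
            raise KeyError(f"edge {p.edge_id} has no label; labeling must be total")
        path = labeling[p.edge_id]
        for k in range(1, len(path) + 1):
            counts[";".join(path[:k])] += 1
    if not counts:
        return pd.Series(dtype=np.int64)
    return pd.Series(counts, dtype=np.int64).sort_index()


def to_jplace(package: ReferencePackage, placements) -> str:
    """Serialize placements to a jplace (version 3) JSON string."""
    doc = {
        "version": 3,
        "tree": package.tree.newick(edge_numbers=True),
        "fields": ["edge_num", "likelihood", "pendant_length"],
        "placements": [
            {"p": [[p.edge_id, p.log_likelihood, p.pendant_length]],
             "n": [p.query_id]}
            for p in placements
        ],
        "metadata": {"invocation": "ecoplace"},
    }
    return json.dumps(doc, indent=1)
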