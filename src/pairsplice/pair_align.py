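"""Pairwise gapped alignment of assembled transcript isoforms.

Implements a seed–chain–extend aligner for transcript-vs-transcript
comparison.  Seeds are exact shared k-mers (default k = 18, no seed
mismatches), merged and extended into maximal exact matching blocks,
then chained by a highest-scoring collinear dynamic program.  Indels
between flanking matched blocks are the raw material for alternative
splicing calls downstream.

Defaults mirror a common BLAT parameterization for cDNA comparison:
tile size 18, no seed mismatch, minimum identity 96%, maximum gap
10,000 nt.  Identity is computed over aligned columns only (gaps are
excluded from the denominator).
"""

from __future__ import annotations

import itertools
from collections import defaultdict
from dataclasses import dataclass, field

from .errors import ValidationError
from .io import TranscriptCluster, check_sequence

#: penalty charged once per inter-block gap when scoring chains
GAP_OPEN_PENALTY = 4


@dataclass(frozen=True)
class AlignParams:
    """Seeding/chaining thresholds for transcript pair alignment."""

    tile_size: int = 18
    allowed_seed_mismatches: int = 0
    min_identity: float = 96.0
    max_gap: int = 10_000
    min_block: int = 18

    def __post_init__(self) -> None:
        if self.tile_size < 8:
            raise ValidationError("tile_size must be >= 8")
        if not (0 <= self.min_identity <= 100):
            raise ValidationError("min_identity must be in [0, 100]")
        if self.max_gap <= 0:
            raise ValidationError("max_gap must be positive")
        if self.allowed_seed_mismatches != 0:
            raise ValidationError("only exact seeding (0 mismatches) is supported")


@dataclass(frozen=True)
class Indel:
    """An insertion present in one transcript of a pair.

    ``carrier`` names which side ("query" or "target") holds the extra
    sequence; both flanks are matched blocks, so terminal overhangs are
    never indels.
    """

    carrier: str
    pos_carrier: int
    length: int
    pos_other: int
    left_flank_len: int
    right_flank_len: int


@dataclass
class AlignmentChain:
    """Ordered collinear matching blocks between two transcripts."""

    query_id: str
    target_id: str
    blocks: list[tuple[int, int, int, int]]  # (q_start, q_end, t_start, t_end)
    indels: list[Indel]
    identity: float
    query_len: int = 0
    target_len: int = 0
    matches: int = 0
    mismatches: int = 0

    @property
    def aligned_columns(self) -> int:
        return self.matches + self.mismatches


def _maximal_exact_blocks(q: str, t: str, k: int) -> list[tuple[int, int, int, int]]:
    """All maximal exact-match blocks seeded by shared k-mers (N never matches)."""
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(t) - k + 1):
        kmer = t[i : i + k]
        if "N" not in kmer:
            index[kmer].append(i)
    by_diag: dict[int, list[int]] = defaultdict(list)
    for j in range(len(q) - k + 1):
        kmer = q[j : j + k]
        if "N" in kmer:
            continue
        for i in index.get(kmer, ()):
            by_diag[i - j].append(j)
    blocks: set[tuple[int, int, int, int]] = set()
    for diag, qs in by_diag.items():
        qs.sort()
        runs: list[tuple[int, int]] = []
        start, end = qs[0], qs[0] + k
        for j in qs[1:]:
            if j <= end:
                end = max(end, j + k)
            else:
                runs.append((start, end))
                start, end = j, j + k
        runs.append((start, end))
        for s, e in runs:
            ts = s + diag
            while s > 0 and ts > 0 and q[s - 1] == t[ts - 1] and q[s - 1] != "N":
                s -= 1
                ts -= 1
            te = e + diag
            while e < len(q) and te < len(t) and q[e] == t[te] and q[e] != "N":
                e += 1
                te += 1
            blocks.add((s, e, s + diag, e + diag))
    return sorted(blocks)


def chain_score(chain: list[tuple[int, int, int, int]]) -> float:
    """Score of an ordered block chain: matched bases minus gap-open penalties.

    Overlapping portions of consecutive blocks are trimmed before counting;
    shared score function for the DP and the brute-force oracle.
    """
    score = 0
    prev_qe = prev_te = None
    for qs, qe, ts, te in chain:
        o = 0
        if prev_qe is not None:
            o = max(prev_qe - qs, prev_te - ts, 0)
        gain = (qe - qs) - o
        if gain <= 0:
            return float("-inf")
        score += gain
        if prev_qe is not None:
            score -= GAP_OPEN_PENALTY
        prev_qe, prev_te = qe, te
    return float(score)


def _chainable(b1, b2) -> bool:
    """Can b2 follow b1 in a collinear chain (after overlap trimming)?"""
    q1s, q1e, t1s, t1e = b1
    q2s, q2e, t2s, t2e = b2
    if q2s < q1s or t2s < t1s:
        return False
    if q2e <= q1e or t2e <= t1e:
        return False
    o = max(q1e - q2s, t1e - t2s, 0)
    return (q2e - q2s) - o > 0


def _best_chain_dp(blocks: list[tuple[int, int, int, int]]) -> list[tuple[int, int, int, int]]:
    """Highest-scoring collinear chain; ties go to the chain whose first
    block starts leftmost on the query (then lexicographically smallest)."""
    n = len(blocks)
    # key per chain end: (score, -first_q_start) maximized
    score = [0.0] * n
    first_q = [0] * n
    prev = [-1] * n
    for i, b in enumerate(blocks):
        score[i] = float(b[1] - b[0])
        first_q[i] = b[0]
        for j in range(i):
            if not _chainable(blocks[j], b):
                continue
            o = max(blocks[j][1] - b[0], blocks[j][3] - b[2], 0)
            cand = score[j] + (b[1] - b[0]) - o - GAP_OPEN_PENALTY
            better = cand > score[i] or (
                cand == score[i] and first_q[j] < first_q[i]
            )
            if better:
                score[i] = cand
                first_q[i] = first_q[j]
                prev[i] = j
    best = max(range(n), key=lambda i: (score[i], -first_q[i], -i))
    chain = []
    i = best
    while i != -1:
        chain.append(blocks[i])
        i = prev[i]
    chain.reverse()
    return chain


def best_chain_bruteforce(blocks: list[tuple[int, int, int, int]]):
    """Exhaustive best-chain search over all ordered block subsets.

    Exponential; intended as an oracle for small instances (<= ~12 blocks).
    """
    blocks = sorted(blocks)
    best = None
    best_key = None
    for r in range(1, len(blocks) + 1):
        for combo in itertools.combinations(blocks, r):
            ok = all(_chainable(combo[i], combo[i + 1]) for i in range(r - 1))
            if not ok:
                continue
            s = chain_score(list(combo))
            key = (s, -combo[0][0])
            if best_key is None or key > best_key:
                best, best_key = list(combo), key
    return best, (best_key[0] if best_key else float("-inf"))


def _trim_chain(chain: list[tuple[int, int, int, int]]) -> list[tuple[int, int, int, int]]:
    out = []
    prev_qe = prev_te = None
    for qs, qe, ts, te in chain:
        if prev_qe is not None:
            o = max(prev_qe - qs, prev_te - ts, 0)
            qs += o
            ts += o
        out.append((qs, qe, ts, te))
        prev_qe, prev_te = qe, te
    return out


def align_pair(
    seq_a: str,
    seq_b: str,
    params: AlignParams | None = None,
    query_id: str = "query",
    target_id: str = "target",
) -> AlignmentChain | None:
    """Align two transcripts; return the best chain or None.

    Returns None when no seed survives, when any gap exceeds
    ``params.max_gap``, or when identity over aligned columns falls
    below ``params.min_identity``.
    """
    params = params or AlignParams()
    q = check_sequence(seq_a, "seq_a")
    t = check_sequence(seq_b, "seq_b")
    blocks = _maximal_exact_blocks(q, t, params.tile_size)
    if not blocks:
        return None
    chain = _trim_chain(_best_chain_dp(blocks))

    matches = sum(qe - qs for qs, qe, ts, te in chain)
    mismatches = 0
    indels: list[Indel] = []
    for (q1s, q1e, t1s, t1e), (q2s, q2e, t2s, t2e) in zip(chain, chain[1:]):
        dq = q2s - q1e
        dt = t2s - t1e
        m = min(dq, dt)
        if m > 0:  # substitution columns, aligned left-justified
            seg_matches = sum(
                1 for x in range(m) if q[q1e + x] == t[t1e + x] and q[q1e + x] != "N"
            )
            matches += seg_matches
            mismatches += m - seg_matches
        r = abs(dq - dt)
        if r > params.max_gap:
            return None
        if r > 0:
            if dq > dt:
                carrier, pos_carrier, pos_other = "query", q1e + m, t1e + m
            else:
                carrier, pos_carrier, pos_other = "target", t1e + m, q1e + m
            indels.append(
                Indel(
                    carrier=carrier,
                    pos_carrier=pos_carrier,
                    length=r,
                    pos_other=pos_other,
                    left_flank_len=q1e - q1s,
                    right_flank_len=q2e - q2s,
                )
            )
    aligned = matches + mismatches
    identity = 100.0 * matches / aligned if aligned else 0.0
    if identity < params.min_identity - 1e-9:
        return None
    return AlignmentChain(
        query_id=query_id,
        target_id=target_id,
        blocks=chain,
        indels=indels,
        identity=identity,
        query_len=len(q),
        target_len=len(t),
        matches=matches,
        mismatches=mismatches,
    )


def all_pairs(cluster: TranscriptCluster, params: AlignParams | None = None) -> list[AlignmentChain]:
    """Align every unordered isoform pair of a cluster; drop failed pairs.

    Clusters with fewer than two isoforms contribute nothing here and are
    counted as constitutive upstream.
    """
    params = params or AlignParams()
    ids = sorted(cluster.isoforms)
    chains = []
    for a, b in itertools.combinations(ids, 2):
        chain = align_pair(cluster.isoforms[a], cluster.isoforms[b], params, query_id=a, target_id=b)
        if chain is not None:
            chains.append(chain)
    return chains


def write_chains_tsv(chains: list[AlignmentChain], path) -> None:
    """Debug writer: one row per block, sim4-like column layout."""
    with open(path, "w") as fh:
        fh.write("query\ttarget\tidentity\tq_start\tq_end\tt_start\tt_end\n")
        for c in chains:
            for qs, qe, ts, te in c.blocks:
                fh.write(f"{c.query_id}\t{c.target_id}\t{c.identity:.2f}\t{qs}\t{qe}\t{ts}\t{te}\n")
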