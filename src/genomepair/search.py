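"""All-vs-all local alignment with Karlin–Altschul E-value statistics.

Optimal Smith–Waterman alignment under affine gap costs is delegated to
Biopython's ``PairwiseAligner`` (exact dynamic programming, no heuristic
seeding); raw scores are converted to bit scores and expectation values with
fixed Karlin–Altschul parameters. Defaults mirror the common protein search
setup (BLOSUM62 with gap open 11 / extend 1) and a +2/−3, 5/2 nucleotide
scheme.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices


class SearchError(ValueError):
    pass


@dataclass(frozen=True)
class KarlinAltschulParams:
    """Extreme-value statistics of a scoring system.

    ``lam`` is in nats per raw-score unit; ``k`` is the dimensionless
    prefactor; ``eff_m``/``eff_n`` are effective query and database lengths
    in residues (raw lengths — no edge correction).
    """

    lam: float
    k: float
    eff_m: int = 1
    eff_n: int = 1

    def __post_init__(self):
        if self.lam <= 0 or self.k <= 0 or self.eff_m < 1 or self.eff_n < 1:
            raise SearchError("invalid Karlin-Altschul parameters")

    def bit_score(self, raw_score: float) -> float:
        return (self.lam * raw_score - math.log(self.k)) / math.log(2)

    def evalue(self, raw_score: float) -> float:
        return self.eff_m * self.eff_n * 2.0 ** (-self.bit_score(raw_score))


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix plus affine gap costs plus Gumbel statistics.

    The gap model is the common convention: a gap of length L costs
    ``gap_open + L * gap_extend``. ``lam``/``k`` are the published gapped
    constants for the default schemes; :func:`ungapped_lambda_k` derives
    ungapped-theory values for arbitrary matrices, and
    :func:`calibrate_gumbel` estimates empirical ones.
    """

    alphabet: str  # "protein" or "nucleotide"
    matrix_name: str = "BLOSUM62"
    match: int = 2  # nucleotide mode only
    mismatch: int = -3
    gap_open: int = 11
    gap_extend: int = 1
    lam: float = 0.267
    k: float = 0.041

    def substitution_matrix(self):
        return _matrix_for(self)


PROTEIN_SCHEME = ScoringScheme(
    alphabet="protein", matrix_name="BLOSUM62",
    gap_open=11, gap_extend=1, lam=0.267, k=0.041,
)
NUCLEOTIDE_SCHEME = ScoringScheme(
    alphabet="nucleotide", match=2, mismatch=-3,
    gap_open=5, gap_extend=2, lam=0.625, k=0.41,
)


@lru_cache(maxsize=8)
def _matrix_cached(alphabet, matrix_name, match, mismatch):
    if alphabet == "protein":
        return substitution_matrices.load(matrix_name)
    letters = "ACGTN"
    arr = substitution_matrices.Array(alphabet=letters, dims=2)
    for a in letters:
        for b in letters:
            if "N" in (a, b):
                arr[a, b] = 0
            else:
                arr[a, b] = match if a == b else mismatch
    return arr


def _matrix_for(scheme: ScoringScheme):
    return _matrix_cached(
        scheme.alphabet, scheme.matrix_name, scheme.match, scheme.mismatch
    )


def make_aligner(scheme: ScoringScheme, mode: str) -> Align.PairwiseAligner:
    """Configured exact DP aligner; ``mode`` is "local" or "global".

    Global mode penalizes end gaps (full-length alignment).
    """
    al = Align.PairwiseAligner()
    al.mode = mode
    al.substitution_matrix = _matrix_for(scheme)
    al.open_gap_score = -(scheme.gap_open + scheme.gap_extend)
    al.extend_gap_score = -scheme.gap_extend
    return al


@dataclass
class LocalHit:
    """One local alignment hit with score statistics (0-based spans)."""

    qid: str
    sid: str
    raw_score: int
    bit_score: float
    evalue: float
    q_span: tuple[int, int]
    s_span: tuple[int, int]
    alphabet: str
    pident_local: float = float("nan")
    length: int = 0
    mismatches: int = 0
    gapopens: int = 0


def _check_alphabet(seq: str, scheme: ScoringScheme, name: str) -> None:
    allowed = set(str(_matrix_for(scheme).alphabet))
    bad = set(seq.upper()) - allowed
    if bad:
        raise SearchError(
            f"{name}: residues {sorted(bad)} not in the {scheme.alphabet} alphabet"
        )


def _alignment_details(aln, matrix):
    """(pident, length, mismatches, gapopens, q_span, s_span) of one alignment."""
    qa, sa = str(aln[0]), str(aln[1])
    ident = mism = gaps = gapopens = 0
    prev_gap = False
    for x, y in zip(qa, sa):
        if x == "-" or y == "-":
            gaps += 1
            if not prev_gap:
                gapopens += 1
            prev_gap = True
        else:
            prev_gap = False
            if x == y:
                ident += 1
            else:
                mism += 1
    length = len(qa)
    pident = 100.0 * ident / length if length else 0.0
    q_span = (int(aln.aligned[0][0][0]), int(aln.aligned[0][-1][1]))
    s_span = (int(aln.aligned[1][0][0]), int(aln.aligned[1][-1][1]))
    return pident, length, mism, gapopens, q_span, s_span


def local_align(
    a: str,
    b: str,
    scheme: ScoringScheme,
    ka: KarlinAltschulParams | None = None,
    qid: str = "query",
    sid: str = "subject",
) -> LocalHit | None:
    """Optimal Smith–Waterman hit between two sequences, or None if score 0.

    When ``ka`` is omitted the raw sequence lengths serve as effective
    lengths.
    """
    if not a or not b:
        raise SearchError("sequences must be non-empty")
    _check_alphabet(a, scheme, qid)
    _check_alphabet(b, scheme, sid)
    if ka is None:
        ka = KarlinAltschulParams(scheme.lam, scheme.k, len(a), len(b))
    aligner = make_aligner(scheme, "local")
    score = aligner.score(a, b)
    if score <= 0:
        return None
    aln = next(iter(aligner.align(a, b)))
    pident, length, mism, gapopens, q_span, s_span = _alignment_details(
        aln, _matrix_for(scheme)
    )
    return LocalHit(
        qid=qid, sid=sid, raw_score=int(round(score)),
        bit_score=ka.bit_score(score), evalue=ka.evalue(score),
        q_span=q_span, s_span=s_span, alphabet=scheme.alphabet,
        pident_local=pident, length=length, mismatches=mism, gapopens=gapopens,
    )


def _score_matrix(seqs_a: list[str], seqs_b: list[str], scheme: ScoringScheme) -> np.ndarray:
    aligner = make_aligner(scheme, "local")
    out = np.zeros((len(seqs_a), len(seqs_b)))
    for i, a in enumerate(seqs_a):
        for j, b in enumerate(seqs_b):
            out[i, j] = aligner.score(a, b)
    return out


def _hits_from_scores(
    ids_q, seqs_q, ids_s, seqs_s, scores, scheme, e_report, details=True
) -> list[LocalHit]:
    total_s = sum(len(s) for s in seqs_s)
    aligner = make_aligner(scheme, "local") if details else None
    hits: list[LocalHit] = []
    for i, qid in enumerate(ids_q):
        ka = KarlinAltschulParams(scheme.lam, scheme.k, len(seqs_q[i]), total_s)
        for j, sid in enumerate(ids_s):
            score = scores[i, j]
            if score <= 0:
                continue
            ev = ka.evalue(score)
            if ev > e_report:
                continue
            hit = LocalHit(
                qid=qid, sid=sid, raw_score=int(round(score)),
                bit_score=ka.bit_score(score), evalue=ev,
                q_span=(0, 0), s_span=(0, 0), alphabet=scheme.alphabet,
            )
            if details:
                aln = next(iter(aligner.align(seqs_q[i], seqs_s[j])))
                (hit.pident_local, hit.length, hit.mismatches,
                 hit.gapopens, hit.q_span, hit.s_span) = _alignment_details(
                    aln, _matrix_for(scheme)
                )
            hits.append(hit)
    hits.sort(key=lambda h: (h.qid, h.evalue, -h.bit_score, h.sid))
    return hits


def _as_id_seq_lists(obj, side):
    """Accept a mapping or an iterable of (id, seq) pairs; enforce unique ids."""
    items = list(obj.items()) if hasattr(obj, "items") else list(obj)
    ids = [i for i, _ in items]
    if len(set(ids)) != len(ids):
        raise SearchError(f"duplicate sequence ids on side {side}")
    return ids, [s for _, s in items]


def all_vs_all(
    A: dict[str, str],
    B: dict[str, str],
    scheme: ScoringScheme,
    e_report: float = 10.0,
    details: bool = True,
) -> list[LocalHit]:
    """Every A-vs-B local hit with evalue <= e_report.

    The effective database length is the total residue count of side B.
    Hits are sorted per query by ascending evalue, then descending bit
    score, then subject id.
    """
    ids_a, seqs_a = _as_id_seq_lists(A, "A")
    ids_b, seqs_b = _as_id_seq_lists(B, "B")
    for ids, seqs in ((ids_a, seqs_a), (ids_b, seqs_b)):
        for i, s in zip(ids, seqs):
            if not s:
                raise SearchError(f"empty sequence for id {i}")
            _check_alphabet(s, scheme, i)
    if e_report <= 0:
        return []
    scores = _score_matrix(seqs_a, seqs_b, scheme)
    return _hits_from_scores(ids_a, seqs_a, ids_b, seqs_b, scores, scheme,
                             e_report, details)


def search_both(
    A: dict[str, str],
    B: dict[str, str],
    scheme: ScoringScheme,
    e_report: float = 10.0,
    details: bool = True,
) -> tuple[list[LocalHit], list[LocalHit]]:
    """(hits A->B, hits B->A) sharing one score pass.

    Smith–Waterman scores are symmetric under a symmetric matrix, so the
    raw-score matrix is computed once; only the effective database length
    (and hence the E-values) differs by direction.
    """
    ids_a, seqs_a = _as_id_seq_lists(A, "A")
    ids_b, seqs_b = _as_id_seq_lists(B, "B")
    if e_report <= 0:
        return [], []
    scores = _score_matrix(seqs_a, seqs_b, scheme)
    ab = _hits_from_scores(ids_a, seqs_a, ids_b, seqs_b, scores, scheme,
                           e_report, details)
    ba = _hits_from_scores(ids_b, seqs_b, ids_a, seqs_a, scores.T, scheme,
                           e_report, details)
    return ab, ba


def hits_to_frame(hits: list[LocalHit]):
    """12-column blast-tab-like table (1-based inclusive coordinates)."""
    import pandas as pd

    rows = [
        {
            "qid": h.qid, "sid": h.sid, "pident_local": round(h.pident_local, 2),
            "length": h.length, "mismatches": h.mismatches,
            "gapopens": h.gapopens,
            "qstart": h.q_span[0] + 1, "qend": h.q_span[1],
            "sstart": h.s_span[0] + 1, "send": h.s_span[1],
            "evalue": h.evalue, "bitscore": round(h.bit_score, 1),
        }
        for h in hits
    ]
    return pd.DataFrame(
        rows,
        columns=["qid", "sid", "pident_local", "length", "mismatches",
                 "gapopens", "qstart", "qend", "sstart", "send", "evalue",
                 "bitscore"],
    )


def ungapped_lambda_k(scheme: ScoringScheme, freqs=None) -> tuple[float, float]:
    """Ungapped Karlin–Altschul lambda (and a crude K) for a scoring scheme.

    lambda solves sum_ij p_i p_j exp(lambda * s_ij) = 1 over the residue
    background ``freqs`` (uniform by default). K is approximated by the
    standard high-score limit K ≈ exp(-lambda * <s>) heuristic and is mainly
    useful for relative comparisons; for the default schemes the published
    constants in the scheme are preferred.
    """
    from scipy.optimize import brentq

    mat = _matrix_for(scheme)
    letters = [c for c in str(mat.alphabet) if c != "N"]
    s = np.array([[mat[a, b] for b in letters] for a in letters], dtype=float)
    if freqs is None:
        freqs = np.full(len(letters), 1.0 / len(letters))
    freqs = np.asarray(freqs, dtype=float)
    p_outer = np.outer(freqs, freqs)
    if (p_outer * s).sum() >= 0:
        raise SearchError("expected score must be negative for local statistics")

    def f(lam):
        return (p_outer * np.exp(lam * s)).sum() - 1.0

    lam = brentq(f, 1e-6, 10.0)
    mean_abs = float((p_outer * np.abs(s)).sum())
    k = float(np.exp(-lam * mean_abs))
    return lam, k


def calibrate_gumbel(
    seqs_a: list[str],
    seqs_b: list[str],
    scheme: ScoringScheme,
    n_samples: int = 200,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Empirical (lambda, K) from shuffled-sequence alignment scores.

    Scores of optimal local alignments between shuffled sequence pairs follow
    a Gumbel law; the method-of-moments fit gives lambda = pi/(sigma*sqrt 6)
    and K from the location parameter mu = ln(K m n)/lambda.
    """
    rng = rng or np.random.default_rng(0)
    aligner = make_aligner(scheme, "local")
    scores = []
    lens = []
    for _ in range(n_samples):
        a = list(seqs_a[rng.integers(len(seqs_a))])
        b = list(seqs_b[rng.integers(len(seqs_b))])
        rng.shuffle(a)
        rng.shuffle(b)
        scores.append(aligner.score("".join(a), "".join(b)))
        lens.append((len(a), len(b)))
    scores = np.asarray(scores, dtype=float)
    sigma = scores.std(ddof=1)
    if sigma == 0:
        raise SearchError("degenerate score distribution; cannot calibrate")
    lam = math.pi / (sigma * math.sqrt(6))
    euler = 0.5772156649015329
    mu = scores.mean() - euler / lam
    mn = float(np.mean([m * n for m, n in lens]))
    k = math.exp(lam * mu) / mn
    return lam, k
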