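"""Decomposition of assembled HKαα sequences and cross-carrier similarity.

An assembled HKαα allele is cut back into its constituent sections —
αααanti4.2 junction segment, special upstream region, undetected gap,
special downstream region, -α3.7 junction segment — by locating the two
recombination-junction signatures and locally aligning the intervening
sequence against the reference to recover reference coordinates (1-based
inclusive, matching the cluster model's bookkeeping).

Junction signatures span each crossover's full homology box plus unique
flanking sequence on both sides: because the paired boxes are identical,
no sequence inside a box is junction-specific, so specificity must come
from the flanks.

Pairwise carrier similarity is computed from global alignment with N
columns excluded from both numerator and denominator, so runs of
undetected sequence never depress identity; near-total identity across
unrelated carriers is the signature of a shared ancestral HKαα event.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import edlib
import numpy as np

from hkalpha.cluster import (
    HkaaCompositionConfig,
    ReferenceCluster,
    StructuralAllele,
    build_synthetic_reference,
    recombine,
    CrossoverSpec,
)

DEFAULT_SCORING = dict(match=1, mismatch=-2, gap_open=-5, gap_extend=-1)


@dataclass(frozen=True)
class LocalAlignment:
    query_start: int  # 1-based inclusive
    query_end: int
    ref_start: int  # 1-based inclusive reference coordinates
    ref_end: int
    strand: str
    identity: float  # over aligned non-N columns
    score: int


@dataclass
class SegmentationResult:
    # ordered (label, LocalAlignment or gap length)
    parts: list[tuple[str, LocalAlignment | int]]

    def section(self, label: str):
        for lab, part in self.parts:
            if lab == label:
                return part
        raise KeyError(label)

    def to_bed(self, ref_name: str) -> str:
        lines = []
        for lab, part in self.parts:
            if isinstance(part, LocalAlignment):
                lines.append(f"{ref_name}\t{part.ref_start - 1}\t{part.ref_end}\t{lab}\t0\t+")
        return "\n".join(lines) + "\n"


class NotHkaaLike(ValueError):
    pass


# --------------------------------------------------------------------------
# Seed-and-extend local alignment
# --------------------------------------------------------------------------


def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    idx: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" in kmer:
            continue
        idx.setdefault(kmer, []).append(i)
    return idx


def local_align(
    query: str,
    reference: str | ReferenceCluster,
    k: int = 15,
    scoring: dict[str, int] | None = None,
    xdrop: int = 30,
    min_score: int = 30,
) -> list[LocalAlignment]:
    """Maximal-scoring non-redundant ungapped local matches (seed & extend).

    Exact k-mer seeds are extended in both directions under an X-drop rule
    with the given match/mismatch scores.  An N on either side is a hard
    stop: an undetected run separates alignments rather than being crossed
    on the strength of chance matches beyond it.  The noise model of the
    assembled carrier sequences is substitutions plus N runs, so extension
    is ungapped; reference intervals are reported 1-based inclusive.
    """
    sc = {**DEFAULT_SCORING, **(scoring or {})}
    if isinstance(reference, ReferenceCluster):
        ref_seq, origin = reference.sequence, reference.coordinate_origin
    else:
        ref_seq, origin = reference, 1
    if len(query) < k:
        raise ValueError(f"query shorter than k={k}; use a smaller seed length")

    idx = _kmer_index(ref_seq, k)
    qb = np.frombuffer(query.encode(), dtype=np.uint8)
    rb = np.frombuffer(ref_seq.encode(), dtype=np.uint8)
    nq, nr = len(qb), len(rb)
    N = ord("N")

    seen_diag: dict[int, list[tuple[int, int]]] = {}
    hits: list[LocalAlignment] = []

    def extend(qs: int, rs: int) -> tuple[int, int, int, int]:
        """Extend the seed [qs, qs+k) / [rs, rs+k) both ways; 0-based bounds."""
        # seed score
        def step_range(q0, r0, direction):
            best_off, best_sc, cur = 0, 0, 0
            off = 0
            while True:
                off += 1
                qi, ri = q0 + direction * off, r0 + direction * off
                if not (0 <= qi < nq and 0 <= ri < nr):
                    break
                if qb[qi] == N or rb[ri] == N:
                    break
                if qb[qi] == rb[ri]:
                    cur += sc["match"]
                else:
                    cur += sc["mismatch"]
                if cur > best_sc:
                    best_sc, best_off = cur, off
                if best_sc - cur > xdrop:
                    break
            return best_off, best_sc

        right_off, right_sc = step_range(qs + k - 1, rs + k - 1, +1)
        left_off, left_sc = step_range(qs, rs, -1)
        q0, q1 = qs - left_off, qs + k - 1 + right_off
        r0, r1 = rs - left_off, rs + k - 1 + right_off
        return q0, q1, r0, r1

    for qs in range(0, nq - k + 1):
        kmer = query[qs : qs + k]
        if "N" in kmer:
            continue
        for rs in idx.get(kmer, ()):
            diag = rs - qs
            covered = False
            for a, b in seen_diag.get(diag, ()):
                if a <= qs and qs + k - 1 <= b:
                    covered = True
                    break
            if covered:
                continue
            q0, q1, r0, r1 = extend(qs, rs)
            seen_diag.setdefault(diag, []).append((q0, q1))
            qcols = qb[q0 : q1 + 1]
            rcols = rb[r0 : r1 + 1]
            informative = (qcols != N) & (rcols != N)
            n_inf = int(informative.sum())
            matches = int(((qcols == rcols) & informative).sum())
            mism = n_inf - matches
            score = matches * sc["match"] + mism * sc["mismatch"]
            if score < min_score:
                continue
            identity = matches / n_inf if n_inf else 0.0
            hits.append(
                LocalAlignment(
                    q0 + 1, q1 + 1, r0 + origin, r1 + origin, "+", identity, score
                )
            )

    # non-redundant: drop alignments whose query interval is contained in a
    # higher-scoring one on the same diagonal-free basis
    hits.sort(key=lambda h: -h.score)
    kept: list[LocalAlignment] = []
    for h in hits:
        redundant = any(
            k2.query_start <= h.query_start and h.query_end <= k2.query_end
            and k2.score >= h.score
            for k2 in kept
        )
        if not redundant:
            kept.append(h)
    kept.sort(key=lambda h: (h.query_start, h.query_end))
    return kept


# --------------------------------------------------------------------------
# Junction motifs and segmentation
# --------------------------------------------------------------------------


def junction_motifs(
    ref: ReferenceCluster | None = None, flank: int = 50
) -> dict[str, str]:
    """Junction signatures built from the constructed D37 and ANTI42 alleles.

    Each signature is the recombination junction's full homology box plus
    ``flank`` bp of the unique sequence on either side, taken from the
    constructed allele itself.
    """
    ref = ref or build_synthetic_reference()
    d37, _ = recombine(ref, CrossoverSpec("Z-alpha2", "Z-alpha1"))
    _, anti42 = recombine(ref, CrossoverSpec("X-alpha2", "X-alpha1"))
    z = ref.feature("Z-alpha2", "homology_box")
    x = ref.feature("X-alpha2", "homology_box")

    def around(allele, junction_pos: int, box_len: int) -> str:
        # junction_pos: 1-based position of the last base of the left segment
        half = box_len // 2
        start = junction_pos - half - flank
        end = junction_pos + (box_len - half) + flank
        return allele.sequence[start - 1 : end]

    d37_junction = len(d37.provenance[0].materialize(ref))
    anti42_junction = len(anti42.provenance[0].materialize(ref))
    return {
        "d37": around(d37, d37_junction, z.length),
        "anti42": around(anti42, anti42_junction, x.length),
    }


def _find_motif(query: str, motif: str, max_divergence: float = 0.05) -> tuple[int, int] | None:
    """Best infix match of motif in query (0-based half-open), or None."""
    res = edlib.align(motif, query, mode="HW", task="locations",
                      k=max(1, int(len(motif) * max_divergence)))
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    s, e = res["locations"][0]
    return s, e + 1


def segment_hkaa_sequence(
    seq: str,
    reference: ReferenceCluster | None = None,
    motifs: dict[str, str] | None = None,
    k: int = 15,
) -> SegmentationResult:
    """Decompose an assembled HKαα sequence into its five labelled parts.

    Expects, in order: the αααanti4.2 junction segment, the special
    upstream region, a run of undetected N, the special downstream region,
    and the -α3.7 junction segment.  The special sub-alignments are reported
    with their reference coordinates; the reference intervals of the two
    special regions may overlap (the shared block the two sections have in
    common is reported as-is for both, not arbitrated).
    """
    reference = reference or build_synthetic_reference()
    motifs = motifs or junction_motifs(reference)

    a42 = _find_motif(seq, motifs["anti42"])
    if a42 is None:
        raise NotHkaaLike("αααanti4.2 junction signature not found")
    d37 = _find_motif(seq, motifs["d37"])
    if d37 is None:
        raise NotHkaaLike("-α3.7 junction signature not found")
    if not a42[1] <= d37[0]:
        raise NotHkaaLike("junction signatures out of expected order")

    inner_start, inner_end = a42[1], d37[0]  # 0-based half-open inner window
    inner = seq[inner_start:inner_end]
    gaps = [(m.start(), m.end()) for m in re.finditer(r"N+", inner)]
    principal = max(gaps, key=lambda g: g[1] - g[0]) if gaps else None

    hits = local_align(seq, reference, k=k)
    origin = reference.coordinate_origin
    qb = seq.encode()
    rb = reference.sequence.encode()

    def hit_containing(qpos0: int) -> LocalAlignment:
        """Best-scoring local alignment covering 0-based query position."""
        best = None
        for h in hits:
            if h.query_start - 1 <= qpos0 <= h.query_end - 1:
                if best is None or h.score > best.score:
                    best = h
        if best is None:
            raise NotHkaaLike(f"no reference alignment covers query position {qpos0 + 1}")
        return best

    def anchored_section(anchor0: int, direction: int) -> LocalAlignment:
        """Exact diagonal extension from a gap-adjacent anchor.

        Extends while bases match on the diagonal; an isolated mismatch is
        bridged when the next 12 diagonal bases match exactly, so sparse
        substitution noise does not truncate a section while extension still
        stops deterministically at the (microhomology-free) splice point.
        """
        h = hit_containing(anchor0)
        diag = (h.ref_start - origin) - (h.query_start - 1)
        N = ord("N")

        def on_diag(p: int) -> bool:
            return 0 <= p < len(qb) and 0 <= p + diag < len(rb)

        def exact_run(p: int, n: int) -> bool:
            return all(
                on_diag(p + direction * i)
                and qb[p + direction * i] != N
                and qb[p + direction * i] == rb[p + direction * i + diag]
                for i in range(n)
            )

        q = anchor0
        last = None
        while on_diag(q):
            if qb[q] != N and qb[q] == rb[q + diag]:
                last = q
                q += direction
                continue
            # substitution or interior N run: bridge it when the diagonal
            # resumes with 12 exact matches, otherwise this is the splice
            p = q
            while on_diag(p) and qb[p] == N:
                p += direction
            if p == q:  # plain mismatch, step over it
                p = q + direction
            if not exact_run(p, 12):
                break
            q = p
        if last is None:
            raise NotHkaaLike("gap-adjacent anchor does not align to the reference")
        lo0, hi0 = (min(anchor0, last), max(anchor0, last))
        qcols = np.frombuffer(qb[lo0 : hi0 + 1], dtype=np.uint8)
        rcols = np.frombuffer(rb[lo0 + diag : hi0 + diag + 1], dtype=np.uint8)
        informative = (qcols != N) & (rcols != N)
        n_inf = int(informative.sum())
        matches = int(((qcols == rcols) & informative).sum())
        identity = matches / n_inf if n_inf else 0.0
        sc = DEFAULT_SCORING
        score = matches * sc["match"] + (n_inf - matches) * sc["mismatch"]
        return LocalAlignment(
            lo0 + 1, hi0 + 1, lo0 + diag + origin, hi0 + diag + origin, "+", identity, score
        )

    def covering(lo: int, hi: int) -> LocalAlignment:
        """Best-scoring alignment whose query interval covers most of [lo,hi)."""
        best, best_cov = None, -1
        for h in hits:
            cov = min(h.query_end, hi) - max(h.query_start, lo + 1) + 1
            if cov > best_cov:
                best, best_cov = h, cov
        if best is None or best_cov <= 0:
            raise NotHkaaLike(f"no reference alignment covers query [{lo + 1},{hi}]")
        # clip to the window so reported coordinates describe the section
        dl = max(0, (lo + 1) - best.query_start)
        dr = max(0, best.query_end - hi)
        return LocalAlignment(
            best.query_start + dl,
            best.query_end - dr,
            best.ref_start + dl,
            best.ref_end - dr,
            best.strand,
            best.identity,
            best.score,
        )

    parts: list[tuple[str, LocalAlignment | int]] = []
    if principal is not None:
        g0, g1 = inner_start + principal[0], inner_start + principal[1]
        upstream = anchored_section(g0 - 1, -1)
        downstream = anchored_section(g1, +1)
        parts.append(("anti42_junction", covering(0, upstream.query_start - 1)))
        parts.append(("special_upstream", upstream))
        parts.append(("undetected_gap", g1 - g0))
        parts.append(("special_downstream", downstream))
        parts.append(("d37_junction", covering(downstream.query_end, len(seq))))
    else:
        parts.append(("anti42_junction", covering(0, a42[1])))
        parts.append(("special_upstream", covering(inner_start, inner_end)))
        parts.append(("d37_junction", covering(d37[0], len(seq))))

    # query intervals must be ordered and non-overlapping
    last = 0
    for lab, part in parts:
        if isinstance(part, LocalAlignment):
            if part.query_start <= last:
                raise NotHkaaLike(f"section {lab} overlaps the previous section")
            last = part.query_end
    return SegmentationResult(parts)


# --------------------------------------------------------------------------
# Cross-carrier similarity
# --------------------------------------------------------------------------


@dataclass
class SimilarityMatrix:
    sample_ids: list[str]
    identity: np.ndarray  # pairwise identity over mutually non-N columns
    same_ancestor_flag: bool
    threshold: float
    incomparable: list[tuple[str, str]]

    def to_tsv(self) -> str:
        header = "\t".join(["sample"] + self.sample_ids)
        lines = [header]
        for i, sid in enumerate(self.sample_ids):
            lines.append(
                "\t".join([sid] + [f"{self.identity[i, j]:.6f}" for j in range(len(self.sample_ids))])
            )
        return "\n".join(lines) + "\n"


def pairwise_identity(a: str, b: str) -> float | None:
    """Identity over aligned, mutually non-N columns of a global alignment.

    Returns None when no informative (non-N) column exists.
    """
    res = edlib.align(a, b, mode="NW", task="path")
    nice = edlib.getNiceAlignment(res, a, b)
    qa, qb = nice["query_aligned"], nice["target_aligned"]
    informative = matches = 0
    for ca, cb in zip(qa, qb):
        if ca in ("N", "-") and cb in ("N", "-") and not (ca == "-" and cb == "-"):
            continue
        if "N" in (ca, cb):
            continue
        informative += 1
        if ca == cb and ca != "-":
            matches += 1
    if informative == 0:
        return None
    return matches / informative


def similarity_analysis(
    sequences: dict[str, str], threshold: float = 0.995
) -> SimilarityMatrix:
    """Pairwise identity matrix and the shared-ancestor flag.

    The flag is true iff the minimum comparable pairwise identity is at
    least the threshold.  Pairs with no informative overlap are reported
    as incomparable and do not contribute to the flag.
    """
    ids = list(sequences)
    if len(ids) < 2:
        raise ValueError("similarity analysis needs at least two sequences")
    n = len(ids)
    mat = np.ones((n, n))
    incomparable = []
    min_identity = 1.0
    for i in range(n):
        for j in range(i + 1, n):
            ident = pairwise_identity(sequences[ids[i]], sequences[ids[j]])
            if ident is None:
                incomparable.append((ids[i], ids[j]))
                mat[i, j] = mat[j, i] = np.nan
                continue
            mat[i, j] = mat[j, i] = ident
            min_identity = min(min_identity, ident)
    flag = min_identity >= threshold
    return SimilarityMatrix(ids, mat, flag, threshold, incomparable)
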