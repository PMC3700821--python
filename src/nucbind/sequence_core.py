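"""Genome representation, motif pattern algebra, and genome scanning.

DNA is held as plain Python strings over ``{A,C,G,T,a,c,g,t,N}`` with
lowercase marking soft-masked (repetitive) sequence.  Motifs are exact
k-mer templates: either continuous (``NNNNNNNN``) or gapped, such as the
glucocorticoid-receptor half-site arrangement ``N-NNN---NNN-N`` (8
informative bases spread over a 13-bp span).  A k-mer and its reverse
complement are treated as one sequence species throughout; the canonical
representative is the lexicographically smaller of the two, which
collapses the 65,536 continuous 8-mers to 32,896 canonical ones.

All coordinates are 0-based half-open (BED semantics).
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "Genome",
    "MotifPattern",
    "MotifOccurrence",
    "CONTINUOUS_8MER",
    "SPLIT_8MER",
    "CONTINUOUS_7MER",
    "get_pattern",
    "revcomp",
    "canonical_kmer",
    "enumerate_kmer_space",
    "scan_genome",
    "one_bp_variants",
    "nearest_neighbor_distances",
    "read_fasta",
    "write_fasta",
    "occurrences_to_bed",
    "occurrences_from_bed",
]

_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

# base -> 2-bit code; 255 marks anything that is not A/C/G/T (any case)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(_BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

# lowercase acgt -> 1 (soft-masked); N and friends also barred from masked scans
_SOFT = np.zeros(256, dtype=bool)
for _b in "acgt":
    _SOFT[ord(_b)] = True


def seq_to_codes(seq: str) -> np.ndarray:
    """2-bit-encode a DNA string; invalid characters become 255."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE[raw]


def seq_soft_mask(seq: str) -> np.ndarray:
    """Boolean array flagging soft-masked (lowercase) positions."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _SOFT[raw]


def revcomp(seq: str) -> str:
    """Reverse complement, case-preserving."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_kmer(kmer: str) -> str:
    """Canonical representative of a k-mer: min(kmer, revcomp) lexicographically.

    Idempotent and strand-symmetric:
    ``canonical_kmer(x) == canonical_kmer(revcomp(x))``.
    """
    if any(c not in _BASES for c in kmer):
        raise ValueError(f"k-mer contains non-ACGT character: {kmer!r}")
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


@functools.lru_cache(maxsize=None)
def _revcomp_code_table(k: int) -> np.ndarray:
    """Lookup table mapping every k-mer code to its reverse-complement code."""
    codes = np.arange(4**k, dtype=np.int64)
    rc = np.zeros_like(codes)
    tmp = codes.copy()
    for _ in range(k):
        rc = rc * 4 + (3 - (tmp % 4))
        tmp //= 4
    return rc


@functools.lru_cache(maxsize=None)
def _canonical_code_table(k: int) -> np.ndarray:
    codes = np.arange(4**k, dtype=np.int64)
    return np.minimum(codes, _revcomp_code_table(k))


def kmer_to_code(kmer: str) -> int:
    code = 0
    for c in kmer:
        code = code * 4 + _BASES.index(c)
    return code


def code_to_kmer(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(_BASES[code % 4])
        code //= 4
    return "".join(reversed(out))


@dataclass(frozen=True)
class MotifPattern:
    """A k-mer template: informative offsets within a window of span L.

    The offset set must map onto itself under ``i -> span - 1 - i`` so that
    the reverse complement of a match is again a match of the same pattern
    (reverse-complement closure), which makes canonicalization well defined.
    """

    offsets: tuple[int, ...]
    span: int
    label: str = ""

    def __post_init__(self) -> None:
        offs = self.offsets
        if list(offs) != sorted(set(offs)):
            raise ValueError("offsets must be strictly increasing")
        if offs[0] < 0 or offs[-1] >= self.span:
            raise ValueError("offsets must lie within [0, span)")
        if not self.is_rc_closed:
            raise ValueError(
                f"pattern {self.label or offs} is not reverse-complement closed"
            )

    @property
    def k(self) -> int:
        return len(self.offsets)

    @property
    def is_rc_closed(self) -> bool:
        return {self.span - 1 - o for o in self.offsets} == set(self.offsets)

    def informative_text(self, window: str) -> str:
        """Extract informative bases of a window of length ``span``."""
        return "".join(window[o] for o in self.offsets)


CONTINUOUS_8MER = MotifPattern(tuple(range(8)), 8, "cont8")
#: GR-like split 8-mer, N-NNN---NNN-N: 8 informative bases in a 13-bp span
SPLIT_8MER = MotifPattern((0, 2, 3, 4, 8, 9, 10, 12), 13, "split8")
CONTINUOUS_7MER = MotifPattern(tuple(range(7)), 7, "cont7")

_PATTERNS = {p.label: p for p in (CONTINUOUS_8MER, SPLIT_8MER, CONTINUOUS_7MER)}


def get_pattern(name: str) -> MotifPattern:
    try:
        return _PATTERNS[name]
    except KeyError:
        raise KeyError(f"unknown pattern {name!r}; known: {sorted(_PATTERNS)}")


def enumerate_kmer_space(pattern: MotifPattern) -> set[str]:
    """All distinct canonical assignments to a pattern's informative positions.

    For even k the count is (4^k + 4^(k/2)) / 2 (palindromes are their own
    reverse complement); for the continuous or split 8-mer this is 32,896.
    """
    if not pattern.is_rc_closed:
        raise ValueError("pattern is not reverse-complement closed")
    k = pattern.k
    canon = np.unique(_canonical_code_table(k))
    return {code_to_kmer(int(c), k) for c in canon}


@dataclass
class Genome:
    """Ordered collection of named chromosomes (soft-masked DNA strings)."""

    chromosomes: dict[str, str]

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("genome has no chromosomes")
        for name, seq in self.chromosomes.items():
            if not seq:
                raise ValueError(f"chromosome {name!r} is empty")
            bad = set(seq) - set("ACGTacgtN")
            if bad:
                raise ValueError(f"chromosome {name!r} has invalid characters {bad}")

    def __iter__(self) -> Iterator[str]:
        return iter(self.chromosomes)

    def __getitem__(self, name: str) -> str:
        return self.chromosomes[name]

    def length(self, name: str) -> int:
        return len(self.chromosomes[name])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self.chromosomes:
            raise KeyError(f"unknown chromosome {chrom!r}")
        return self.chromosomes[chrom][start:end]


@dataclass(frozen=True)
class MotifOccurrence:
    """One genomic match of a motif pattern.

    ``matched_text`` holds the informative bases read on the + strand;
    ``canonical_id`` is its canonical form.
    """

    chrom: str
    start: int
    end: int
    strand: str
    matched_text: str
    canonical_id: str

    @property
    def center(self) -> int:
        # even spans floor to the left-of-middle base
        return self.start + (self.end - self.start) // 2


def _window_kmer_codes(
    codes: np.ndarray, offsets: Sequence[int], span: int
) -> tuple[np.ndarray, np.ndarray]:
    """Forward informative-base codes for every window start, plus validity."""
    n_win = len(codes) - span + 1
    if n_win <= 0:
        empty = np.zeros(0, dtype=np.int64)
        return empty, np.zeros(0, dtype=bool)
    fwd = np.zeros(n_win, dtype=np.int64)
    valid = np.ones(n_win, dtype=bool)
    for off in offsets:
        c = codes[off : off + n_win]
        valid &= c != 255
        fwd = fwd * 4 + np.where(c == 255, 0, c).astype(np.int64)
    return fwd, valid


def scan_genome(
    genome: Genome,
    pattern: MotifPattern,
    target: str = "all",
    use_masked: bool = True,
) -> list[MotifOccurrence]:
    """Find every window whose informative bases match ``target`` on either strand.

    A palindromic match (forward text equal to its reverse complement) is
    reported once, on strand "+".  With ``use_masked`` any window touching a
    soft-masked or N base (informative or gap position) is skipped; without
    it matching is case-insensitive but N never matches.  ``target`` may be
    a canonical k-mer of the pattern's space or ``"all"``.
    """
    k = pattern.k
    rc_table = _revcomp_code_table(k)
    target_code = None
    if target != "all":
        if len(target) != k:
            raise ValueError(f"target length {len(target)} != pattern k {k}")
        tc = kmer_to_code(target)
        if int(rc_table[tc]) < tc:
            raise ValueError(f"target {target!r} is not canonical")
        target_code = tc

    occurrences: list[MotifOccurrence] = []
    for chrom, seq in genome.chromosomes.items():
        codes = seq_to_codes(seq)
        fwd, valid = _window_kmer_codes(codes, pattern.offsets, pattern.span)
        if fwd.size == 0:
            continue
        if use_masked:
            soft = seq_soft_mask(seq)
            bad = soft | (codes == 255)
            # window invalid if any base of the full span is masked/N
            cs = np.concatenate(([0], np.cumsum(bad)))
            valid &= (cs[pattern.span : pattern.span + fwd.size] - cs[: fwd.size]) == 0
        rc = rc_table[fwd]
        canon = np.minimum(fwd, rc)
        if target_code is None:
            hits = np.flatnonzero(valid)
        else:
            hits = np.flatnonzero(valid & (canon == target_code))
        for s in hits:
            f = int(fwd[s])
            c = int(canon[s])
            text = code_to_kmer(f, k)
            strand = "+" if f == c else "-"
            if target_code is not None:
                strand = "+" if f == target_code else "-"
            occurrences.append(
                MotifOccurrence(
                    chrom=chrom,
                    start=int(s),
                    end=int(s) + pattern.span,
                    strand=strand,
                    matched_text=text,
                    canonical_id=code_to_kmer(c, k),
                )
            )
    return occurrences


def one_bp_variants(
    motif: str,
    pattern: MotifPattern,
    exclude: Iterable[str] = (),
) -> set[str]:
    """Canonical k-mers at Hamming distance exactly 1 from ``motif``.

    The motif itself and any additional canonical motifs in ``exclude``
    (e.g. the CG-variant of the canonical motif) are removed from the set.
    """
    if len(motif) != pattern.k:
        raise ValueError("motif length does not match pattern")
    canon_self = canonical_kmer(motif)
    drop = {canon_self} | {canonical_kmer(e) for e in exclude}
    variants: set[str] = set()
    for i in range(len(motif)):
        for b in _BASES:
            if b == motif[i]:
                continue
            var = motif[:i] + b + motif[i + 1 :]
            cv = canonical_kmer(var)
            if cv not in drop:
                variants.add(cv)
    return variants


def nearest_neighbor_distances(
    occurrences: Sequence[MotifOccurrence],
) -> np.ndarray:
    """Center-to-center distance from each occurrence to its nearest homotypic
    neighbor on the same chromosome; lone occurrences get +inf."""
    n = len(occurrences)
    out = np.full(n, np.inf)
    by_chrom: dict[str, list[int]] = {}
    for i, occ in enumerate(occurrences):
        by_chrom.setdefault(occ.chrom, []).append(i)
    for idxs in by_chrom.values():
        if len(idxs) < 2:
            continue
        centers = np.array([occurrences[i].center for i in idxs], dtype=float)
        order = np.argsort(centers, kind="stable")
        sc = centers[order]
        gaps = np.diff(sc)
        nearest = np.empty(len(sc))
        nearest[0] = gaps[0]
        nearest[-1] = gaps[-1]
        if len(sc) > 2:
            nearest[1:-1] = np.minimum(gaps[:-1], gaps[1:])
        for pos, oi in enumerate(order):
            out[idxs[oi]] = nearest[pos]
    return out


# ---------------------------------------------------------------------------
# FASTA / BED I/O

def read_fasta(path) -> Genome:
    """Read a (soft-masked) multi-FASTA into a Genome, preserving case."""
    from Bio import SeqIO

    chroms = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    return Genome(chroms)


def write_fasta(genome: Genome, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.chromosomes.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def occurrences_to_bed(occurrences: Sequence[MotifOccurrence], path) -> None:
    """BED6: name = canonical_id, score = 0."""
    with open(path, "w") as fh:
        for occ in occurrences:
            fh.write(
                f"{occ.chrom}\t{occ.start}\t{occ.end}\t{occ.canonical_id}\t0\t{occ.strand}\n"
            )


def occurrences_from_bed(path, pattern: MotifPattern | None = None) -> list[MotifOccurrence]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            name = f[3] if len(f) > 3 else ""
            strand = f[5] if len(f) > 5 else "+"
            out.append(
                MotifOccurrence(chrom, start, end, strand, name, name and canonical_kmer(name) or name)
            )
    return out
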