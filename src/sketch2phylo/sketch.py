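"""Bottom-s MinHash sketching of genome k-mer sets.

A genome is decomposed into its set of canonical k-mers — for every window of
k unambiguous bases, the lexicographically smaller of the k-mer and its
reverse complement. Each canonical k-mer is packed into 2 bits per base,
hashed with a seeded 64-bit mixer, and the ``sigma`` smallest hash values
form the genome's *bottom sketch*. Merging two sketches and counting shared
values among the ``sigma`` smallest of the union yields an estimate of the
Jaccard index of the full k-mer sets, which downstream modules convert into
an uncorrected p-distance and then into an evolutionary distance.

The hash is a MurmurHash3-style finalizer over the packed k-mer XORed with a
mixed seed; it is a bijection on 64-bit words for every seed, so distinct
k-mers never collide and the bottom-``sigma`` values are a uniform random
sample of the k-mer set.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "GenomeRecord",
    "SketchParams",
    "Sketch",
    "JaccardEstimate",
    "read_fasta",
    "choose_k",
    "canonical_kmers",
    "canonical_kmer_codes",
    "bottom_sketch",
    "estimate_jaccard",
    "exact_jaccard",
    "resolve_sketch_params",
    "write_sketch",
    "read_sketch",
    "reverse_complement",
]

GAP = 4  # shared residue-code convention: A=0 C=1 G=2 T=3, gap/ambiguous=4

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate(b"ACGT"):
    _ENCODE[_c] = _i
for _i, _c in enumerate(b"acgt"):
    _ENCODE[_c] = _i

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

_M1 = np.uint64(0xFF51AFD7ED558CCD)
_M2 = np.uint64(0xC4CEB9FE1A85EC53)
_MASK64 = 0xFFFFFFFFFFFFFFFF


def encode(seq: str) -> np.ndarray:
    """Map a nucleotide string to uint8 codes; non-ACGT symbols map to 4."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


_DECODE = np.frombuffer(b"ACGT-", dtype=np.uint8)


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode` for unambiguous codes (4 renders as ``-``)."""
    return bytes(_DECODE[np.asarray(codes, dtype=np.uint8)]).decode("ascii")


def reverse_complement(seq: str) -> str:
    return "".join(_COMP.get(c, "N") for c in reversed(seq.upper()))


@dataclass(frozen=True)
class GenomeRecord:
    """One genome: a taxon label plus one or more contig sequences.

    Contigs are kept separate so that k-mer windows never span contig
    boundaries, while length and base composition are computed over the
    concatenation.
    """

    name: str
    contigs: tuple[str, ...]

    @classmethod
    def from_sequence(cls, name: str, sequence: str) -> "GenomeRecord":
        return cls(name=name, contigs=(sequence.upper(),))

    @property
    def sequence(self) -> str:
        return "".join(self.contigs)

    @property
    def g(self) -> int:
        """Total genome length in bases (including ambiguous symbols)."""
        return sum(len(c) for c in self.contigs)

    @property
    def base_counts(self) -> np.ndarray:
        counts = np.zeros(4, dtype=np.int64)
        for contig in self.contigs:
            codes = encode(contig)
            counts += np.bincount(codes[codes < 4], minlength=4)
        return counts

    @property
    def n_acgt(self) -> int:
        return int(self.base_counts.sum())

    @property
    def freqs(self) -> np.ndarray:
        """Nucleotide frequencies over unambiguous residues only."""
        counts = self.base_counts
        total = counts.sum()
        if total == 0:
            raise ValueError(f"{self.name}: no unambiguous residues")
        return counts / total


def read_fasta(path, name: str | None = None) -> GenomeRecord:
    """Read a (possibly gzip-compressed) FASTA file as one genome.

    All records become contigs of a single :class:`GenomeRecord`; the taxon
    label defaults to the file stem.
    """
    p = Path(path)
    with open(p, "rb") as fh:
        magic = fh.read(2)
    handle = gzip.open(p, "rt") if magic == b"\x1f\x8b" else open(p)
    try:
        first = handle.readline()
        while first and not first.strip():
            first = handle.readline()
        if not first:
            raise ValueError(f"{p}: empty genome")
        if not first.lstrip().startswith(">"):
            raise ValueError(f"{p}: not FASTA (missing '>' header)")
        handle.seek(0)
        records = list(SeqIO.parse(handle, "fasta"))
    finally:
        handle.close()
    contigs = tuple(str(r.seq).upper() for r in records if len(r.seq) > 0)
    if not contigs:
        raise ValueError(f"{p}: empty genome")
    if name is None:
        name = p.name
        if name.endswith(".gz"):
            name = name[:-3]
        for suffix in (".fa", ".fasta", ".fna", ".fas", ".fsa"):
            if name.endswith(suffix):
                name = name[: -len(suffix)]
                break
    return GenomeRecord(name=name, contigs=contigs)


def choose_k(g: int, q: float) -> int:
    """k-mer size from genome length and the random-match probability q.

    ``k = ceil(log4(g(1-q)/q) - 0.5)``, clamped below at 1: the smallest k
    for which the chance of two unrelated genomes of length g sharing a
    random k-mer stays below q.
    """
    if not 0.0 < q < 1.0:
        raise ValueError(f"q must lie in (0, 1), got {q}")
    if g < 1:
        raise ValueError(f"genome length must be positive, got {g}")
    return max(1, math.ceil(math.log(g * (1.0 - q) / q, 4) - 0.5))


def _window_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Canonical packed codes of all fully-unambiguous k-windows."""
    L = codes.size
    if L < k:
        return np.empty(0, dtype=np.uint64)
    w = L - k + 1
    c = codes.astype(np.uint64)
    bad = (codes >= 4).astype(np.int64)
    cum = np.concatenate(([0], np.cumsum(bad)))
    ok = (cum[k:] - cum[:-k]) == 0
    fwd = np.zeros(w, dtype=np.uint64)
    rc = np.zeros(w, dtype=np.uint64)
    three = np.uint64(3)
    for j in range(k):
        s = c[j : j + w]
        fwd |= s << np.uint64(2 * (k - 1 - j))
        rc |= ((three - s) & three) << np.uint64(2 * j)
    return np.minimum(fwd, rc)[ok]


def canonical_kmer_codes(rec: GenomeRecord, k: int) -> np.ndarray:
    """Sorted unique canonical k-mer codes of a genome (per-contig windows)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > 31:
        raise ValueError("k > 31 does not fit 2-bit packing in 64 bits")
    parts = [_window_codes(encode(contig), k) for contig in rec.contigs]
    if not parts:
        return np.empty(0, dtype=np.uint64)
    return np.unique(np.concatenate(parts))


def _code_to_kmer(code: int, k: int) -> str:
    return "".join("ACGT"[(int(code) >> shift) & 3] for shift in range(2 * (k - 1), -1, -2))


def canonical_kmers(rec: GenomeRecord, k: int) -> set[str]:
    """The set of canonical k-mer strings (windows with ambiguity skipped)."""
    return {_code_to_kmer(c, k) for c in canonical_kmer_codes(rec, k)}


def _mix64(x: np.ndarray) -> np.ndarray:
    x = x.astype(np.uint64, copy=True)
    x ^= x >> np.uint64(33)
    x *= _M1
    x ^= x >> np.uint64(33)
    x *= _M2
    x ^= x >> np.uint64(33)
    return x


def hash_kmers(codes: np.ndarray, seed: int) -> np.ndarray:
    """Seeded 64-bit hash of packed k-mer codes (bijective for every seed)."""
    key = _mix64(np.array([seed & _MASK64], dtype=np.uint64))[0]
    return _mix64(codes.astype(np.uint64) ^ key)


@dataclass(frozen=True)
class SketchParams:
    """Concrete sketching parameters; ``q``/``s`` record their provenance."""

    k: int
    sigma: int
    seed: int = 42
    q: float | None = None
    s: float | None = None

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.sigma < 1:
            raise ValueError("sigma must be >= 1")


def resolve_sketch_params(
    records: Sequence[GenomeRecord],
    *,
    k: int | None = None,
    q: float | None = None,
    sigma: int | None = None,
    s: float | None = None,
    seed: int = 42,
) -> SketchParams:
    """Resolve (k|q) and (sigma|s) into concrete parameters for a genome set.

    When derived from ``q``, k uses the largest genome length of the set;
    when derived from ``s``, sigma is ``round(s * mean genome length)``.
    """
    if (k is None) == (q is None):
        raise ValueError("exactly one of k and q must be given")
    if (sigma is None) == (s is None):
        raise ValueError("exactly one of sigma and s must be given")
    lengths = [rec.g for rec in records]
    if not lengths:
        raise ValueError("no genomes given")
    if k is None:
        k = choose_k(max(lengths), q)
    if sigma is None:
        if not 0.0 < s <= 1.0:
            raise ValueError(f"s must lie in (0, 1], got {s}")
        sigma = max(1, round(s * float(np.mean(lengths))))
    return SketchParams(k=k, sigma=sigma, seed=seed, q=q, s=s)


@dataclass(frozen=True)
class Sketch:
    """Bottom-sigma MinHash signature of one genome plus its metadata."""

    taxon: str
    k: int
    sigma: int
    seed: int
    g: int
    n_acgt: int
    freqs: np.ndarray
    hashes: np.ndarray  # uint64, strictly increasing, len <= sigma

    def compatible_with(self, other: "Sketch") -> bool:
        return self.k == other.k and self.seed == other.seed and self.sigma == other.sigma


@dataclass(frozen=True)
class JaccardEstimate:
    j_hat: float
    shared: int
    denom: int


def bottom_sketch(rec: GenomeRecord, params: SketchParams) -> Sketch:
    """Hash all canonical k-mers and keep the sigma smallest distinct values."""
    codes = canonical_kmer_codes(rec, params.k)
    if codes.size == 0:
        raise ValueError(f"{rec.name}: no k-mers (no unambiguous window of length {params.k})")
    freqs = rec.freqs  # raises on all-ambiguous genomes
    hashes = np.sort(hash_kmers(codes, params.seed))[: params.sigma]
    return Sketch(
        taxon=rec.name,
        k=params.k,
        sigma=params.sigma,
        seed=params.seed,
        g=rec.g,
        n_acgt=rec.n_acgt,
        freqs=freqs,
        hashes=hashes,
    )


def estimate_jaccard(a: Sketch, b: Sketch) -> JaccardEstimate:
    """Mash-style merged estimator of the Jaccard index of two k-mer sets.

    The sigma smallest values of the merged sketches stand in for a uniform
    sample of the union; members of that sample present in both sketches
    stand in for the intersection.
    """
    if not a.compatible_with(b):
        raise ValueError(
            "incompatible sketches: "
            f"(k={a.k}, sigma={a.sigma}, seed={a.seed}) vs (k={b.k}, sigma={b.sigma}, seed={b.seed})"
        )
    merged = np.union1d(a.hashes, b.hashes)
    u = merged[: min(a.sigma, merged.size)]
    inter = np.intersect1d(a.hashes, b.hashes, assume_unique=True)
    if inter.size == 0 or u.size == 0:
        shared = 0
    else:
        shared = int(np.searchsorted(inter, u[-1], side="right"))
    denom = int(u.size)
    return JaccardEstimate(j_hat=shared / denom, shared=shared, denom=denom)


def exact_jaccard(a: GenomeRecord, b: GenomeRecord, k: int) -> float:
    """Exact Jaccard index over the full canonical k-mer sets."""
    ka = canonical_kmer_codes(a, k)
    kb = canonical_kmer_codes(b, k)
    if ka.size == 0 and kb.size == 0:
        raise ValueError("both genomes have empty k-mer sets")
    inter = np.intersect1d(ka, kb, assume_unique=True).size
    union = ka.size + kb.size - inter
    return inter / union


# -- flat sketch persistence -------------------------------------------------

_HEADER_TAG = "#sketch2phylo-sketch"


def write_sketch(sk: Sketch, path) -> None:
    """Write a sketch as plain text: one metadata header, one hash per line."""
    if any(ch in sk.taxon for ch in "\t\n"):
        raise ValueError("taxon labels must not contain tabs or newlines")
    pi = ",".join(format(x, ".17g") for x in sk.freqs)
    header = (
        f"{_HEADER_TAG}\ttaxon={sk.taxon}\tk={sk.k}\tsigma={sk.sigma}\tseed={sk.seed}"
        f"\tg={sk.g}\tn_acgt={sk.n_acgt}\tpi={pi}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for h in sk.hashes:
            fh.write(f"{int(h)}\n")


def read_sketch(path) -> Sketch:
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        fields = header.split("\t")
        if fields[0] != _HEADER_TAG:
            raise ValueError(f"{path}: not a sketch file")
        meta = dict(f.split("=", 1) for f in fields[1:])
        hashes = np.array([int(line) for line in fh if line.strip()], dtype=np.uint64)
    return Sketch(
        taxon=meta["taxon"],
        k=int(meta["k"]),
        sigma=int(meta["sigma"]),
        seed=int(meta["seed"]),
        g=int(meta["g"]),
        n_acgt=int(meta["n_acgt"]),
        freqs=np.array([float(x) for x in meta["pi"].split(",")]),
        hashes=hashes,
    )
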