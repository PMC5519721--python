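"""Core containers shared across the pipeline.

Coordinate conventions
----------------------
Internally every genomic coordinate is 0-based, half-open (BED style).
VCF/GFF3 adapters convert at the boundary: a 1-based position ``p`` maps to
internal ``p - 1``.  Interval tracks use BED semantics, so a 1-based query
position ``q`` tests containment of ``q - 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DNA = frozenset("ACGT")

FUNC_CLASSES = ("intronic", "synonymous", "non-synonymous", "LOF", "other")
ELEMENT_TYPES = ("ESE", "ESS", "ISE")


class FormatError(ValueError):
    """Malformed input file."""


class ConfigurationError(ValueError):
    """Invalid configuration or parameter value."""


@dataclass
class Variant:
    """A biallelic SNP with ancestral state and functional class.

    ``pos`` is 1-based (VCF convention); ``pos0`` gives the internal
    0-based coordinate.  ``counts`` maps population label to
    ``(n_haplotypes, n_alt)``.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    ancestral: str | None = None
    func_class: str = "other"
    vid: str | None = None
    counts: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")
        if self.ref not in DNA or self.alt not in DNA:
            raise ValueError(f"non-ACGT allele at {self.chrom}:{self.pos}")
        if self.ancestral is not None and self.ancestral not in (self.ref, self.alt):
            raise ValueError(
                f"ancestral allele {self.ancestral!r} matches neither ref nor alt "
                f"at {self.chrom}:{self.pos}"
            )
        if self.vid is None:
            self.vid = f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @property
    def pos0(self) -> int:
        return self.pos - 1

    @property
    def derived(self) -> str | None:
        """The non-ancestral allele, or None when ancestral state is unknown."""
        if self.ancestral is None:
            return None
        return self.alt if self.ancestral == self.ref else self.ref


@dataclass
class MotifSet:
    """A deduplicated set of hexamer motifs of one element type (ESE/ESS/ISE)."""

    element_type: str
    hexamers: frozenset[str]

    def __post_init__(self) -> None:
        if self.element_type not in ELEMENT_TYPES:
            raise ConfigurationError(f"unknown element type {self.element_type!r}")
        self.hexamers = frozenset(self.hexamers)
        for h in self.hexamers:
            if len(h) != 6 or set(h) - DNA:
                raise ConfigurationError(f"invalid hexamer {h!r}")

    def __contains__(self, hexamer: str) -> bool:
        return hexamer in self.hexamers

    def __len__(self) -> int:
        return len(self.hexamers)


class IntervalTrack:
    """Per-chromosome sorted, non-overlapping half-open intervals with values.

    Used for the background-selection B-value track.  Lookup is by binary
    search; a position covered by no interval returns None.
    """

    def __init__(self, intervals: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        # chrom -> (starts, ends, values); starts/ends 0-based half-open
        self._data = {}
        for chrom, (starts, ends, values) in intervals.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=float)
            order = np.argsort(starts)
            starts, ends, values = starts[order], ends[order], values[order]
            if np.any(ends[:-1] > starts[1:]):
                raise FormatError(f"overlapping intervals on {chrom}")
            if np.any(ends <= starts):
                raise FormatError(f"empty interval on {chrom}")
            self._data[chrom] = (starts, ends, values)

    def lookup(self, chrom: str, pos: int) -> float | None:
        """Value covering 1-based position ``pos``, or None."""
        if chrom not in self._data:
            return None
        starts, ends, values = self._data[chrom]
        q = pos - 1  # BED semantics
        i = int(np.searchsorted(starts, q, side="right")) - 1
        if i >= 0 and q < ends[i]:
            return float(values[i])
        return None

    def lookup_many(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Vectorised lookup; positions 1-based; NaN where uncovered."""
        out = np.full(len(pos), np.nan)
        if chrom not in self._data:
            return out
        starts, ends, values = self._data[chrom]
        q = np.asarray(pos, dtype=np.int64) - 1
        i = np.searchsorted(starts, q, side="right") - 1
        ok = (i >= 0) & (q < ends[np.clip(i, 0, len(ends) - 1)])
        out[ok] = values[i[ok]]
        return out


@dataclass
class HaplotypePanel:
    """Phased haplotypes for one population.

    ``haplotypes`` is an (n_hap, n_sites) 0/1 matrix where 1 codes the ALT
    allele.  ``positions`` are 1-based physical bp, strictly increasing;
    ``genetic_pos`` are the matching genetic-map positions in cM.
    """

    population: str
    haplotypes: np.ndarray
    positions: np.ndarray
    genetic_pos: np.ndarray
    chrom: str = "1"

    def __post_init__(self) -> None:
        self.haplotypes = np.ascontiguousarray(self.haplotypes, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.genetic_pos = np.asarray(self.genetic_pos, dtype=float)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotype matrix must be 2-D")
        if self.haplotypes.shape[1] != len(self.positions):
            raise ValueError("positions do not match haplotype matrix")
        if len(self.positions) > 1 and np.any(np.diff(self.positions) <= 0):
            raise FormatError("positions must be strictly increasing")
        if np.any(np.diff(self.genetic_pos) < 0):
            raise FormatError("genetic positions must be non-decreasing")

    @property
    def n_hap(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    def alt_freq(self) -> np.ndarray:
        return self.haplotypes.mean(axis=0)

    def alt_count(self) -> np.ndarray:
        return self.haplotypes.sum(axis=0)


@dataclass
class Transcript:
    """One isoform: ordered exons as 0-based half-open (start, end) pairs."""

    tid: str
    exons: list[tuple[int, int]]

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


@dataclass
class GeneModel:
    """A gene with its isoforms and skipped-exon flags.

    An exon is flagged skipped iff it is present in at least one isoform and
    absent from at least one other isoform of the same gene while both its
    flanking exons are shared by that other isoform.
    """

    gid: str
    chrom: str
    strand: str
    transcripts: list[Transcript]
    cds: list[tuple[int, int]] | None = None  # 0-based half-open, genomic order

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise FormatError(f"bad strand {self.strand!r} for {self.gid}")
        self._skipped: set[tuple[int, int]] | None = None

    @property
    def span(self) -> tuple[int, int]:
        s = min(t.span[0] for t in self.transcripts)
        e = max(t.span[1] for t in self.transcripts)
        return s, e

    @property
    def exons(self) -> list[tuple[int, int]]:
        """Union of exons over isoforms, sorted."""
        out = set()
        for t in self.transcripts:
            out.update(t.exons)
        return sorted(out)

    def skipped_exons(self) -> set[tuple[int, int]]:
        if self._skipped is not None:
            return self._skipped
        skipped: set[tuple[int, int]] = set()
        sets = [set(t.exons) for t in self.transcripts]
        for t in self.transcripts:
            for i in range(1, len(t.exons) - 1):
                e, prev_e, next_e = t.exons[i], t.exons[i - 1], t.exons[i + 1]
                for other in sets:
                    if e not in other and prev_e in other and next_e in other:
                        skipped.add(e)
                        break
        self._skipped = skipped
        return skipped

    def introns(self, transcript: Transcript | None = None) -> list[tuple[int, int]]:
        """Intronic intervals of one isoform (default: union-exon gaps)."""
        exons = transcript.exons if transcript is not None else self._merged_exons()
        return [
            (exons[i][1], exons[i + 1][0])
            for i in range(len(exons) - 1)
            if exons[i + 1][0] > exons[i][1]
        ]

    def _merged_exons(self) -> list[tuple[int, int]]:
        merged: list[list[int]] = []
        for s, e in self.exons:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        return [(s, e) for s, e in merged]
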