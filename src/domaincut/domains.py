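"""Domain annotations: segment lists, chopping strings, per-residue labels.

A chain of length ``L`` is partitioned (possibly partially — linker residues
may belong to no domain) into domains, each a set of one or more contiguous
sequence segments. Domains carry ordinal labels 1, 2, 3, ... assigned by the
position of each domain's first residue; the labels are arbitrary bookkeeping
and are realigned by stable-marriage matching during assessment.

The text encoding is the CATH-style chopping string: segments of one domain
joined by ``,``, domains joined by ``/`` — e.g. ``"1-50,151-200/51-150"`` is a
discontinuous first domain (residues 1-50 and 151-200) around a second domain
(51-150).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Segment", "DomainAnnotation", "parse_chopping", "label_residues"]


@dataclass(frozen=True)
class Segment:
    """A contiguous run of residues, 1-based inclusive."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid segment {self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def __str__(self) -> str:
        return f"{self.start}-{self.end}"


@dataclass
class DomainAnnotation:
    """A (possibly partial) partition of residues 1..length into domains.

    ``domains`` is a list of segment lists; domain ``k`` (0-based here) has
    ordinal label ``k+1``. Domains are stored sorted by first residue, and
    segments within a domain sorted by start.
    """

    length: int
    domains: list[list[Segment]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("length must be >= 1")
        cleaned = []
        for segs in self.domains:
            if not segs:
                raise ValueError("empty domain (no segments)")
            segs = sorted(segs, key=lambda s: s.start)
            for s in segs:
                if s.end > self.length:
                    raise ValueError(f"segment {s} exceeds chain length {self.length}")
            cleaned.append(segs)
        cleaned.sort(key=lambda segs: segs[0].start)
        self.domains = cleaned
        # disjointness across all segments of all domains
        covered = np.zeros(self.length, dtype=bool)
        for segs in self.domains:
            for s in segs:
                window = covered[s.start - 1 : s.end]
                if window.any():
                    raise ValueError(f"overlapping segment {s}")
                window[:] = True

    @property
    def n_domains(self) -> int:
        return len(self.domains)

    @classmethod
    def from_cuts(cls, length: int, cuts: list[int]) -> "DomainAnnotation":
        """Contiguous partition [1, c1-1], [c1, c2-1], ..., [ck, L] from sorted cut points."""
        cuts = sorted(set(int(c) for c in cuts))
        for c in cuts:
            if not (1 < c <= length):
                raise ValueError(f"cut point {c} outside (1, {length}]")
        starts = [1] + cuts
        ends = cuts_to_ends = [c - 1 for c in cuts] + [length]
        return cls(length, [[Segment(s, e)] for s, e in zip(starts, cuts_to_ends)])

    @classmethod
    def single_domain(cls, length: int) -> "DomainAnnotation":
        return cls(length, [[Segment(1, length)]])

    def boundaries(self) -> list[int]:
        """First residues of each domain after the first (cut points), for
        contiguous predictions."""
        return [segs[0].start for segs in self.domains[1:]]

    def to_chopping(self) -> str:
        return "/".join(",".join(str(s) for s in segs) for segs in self.domains)

    def __str__(self) -> str:
        return self.to_chopping()


def parse_chopping(text: str, length: int) -> DomainAnnotation:
    """Parse a chopping string like ``"1-50,151-200/51-150"`` into an annotation.

    Raises ``ValueError`` naming the offending token on reversed ranges,
    out-of-range residues, or overlap between domains.
    """
    text = text.strip()
    if not text:
        raise ValueError("empty chopping string")
    domains: list[list[Segment]] = []
    for dom_text in text.split("/"):
        segs = []
        for seg_text in dom_text.split(","):
            seg_text = seg_text.strip()
            try:
                start_s, end_s = seg_text.split("-")
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ValueError(f"malformed segment {seg_text!r}") from None
            if start > end:
                raise ValueError(f"reversed range {seg_text!r}")
            if end > length:
                raise ValueError(f"segment {seg_text!r} exceeds chain length {length}")
            segs.append(Segment(start, end))
        domains.append(segs)
    return DomainAnnotation(length, domains)  # overlap checked in constructor


def label_residues(ann: DomainAnnotation) -> np.ndarray:
    """Per-residue label vector, length L; label 0 means linker (unlabeled).

    Residues in any segment of domain k get ordinal label k+1; discontinuous
    segments of one domain share its label.
    """
    labels = np.zeros(ann.length, dtype=np.int64)
    for k, segs in enumerate(ann.domains, start=1):
        for s in segs:
            labels[s.start - 1 : s.end] = k
    return labels
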