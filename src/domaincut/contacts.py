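"""Residue contact lists and structure-derived contacts.

Reads and writes ranked contact lists in CASP RR format, parses Cα-only
chains from PDB files, and derives contacts from coordinates using a
pseudo-Cβ construction: for three consecutive Cα atoms C1, C2, C3 the
pseudo-Cβ of the middle residue is the point 2 Å from C2 along the direction
away from the C1–C3 line — an approximation of the side-chain direction that
needs no atoms beyond the backbone trace. Two residues are in contact when
their pseudo-Cβ distance is at most 8 Å.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Contact",
    "ContactList",
    "ChainCoords",
    "read_rr",
    "write_rr",
    "read_ca_coords",
    "write_ca_pdb",
    "pseudo_cbeta",
    "derive_structure_contacts",
    "filter_contacts",
]

PSEUDO_CB_OFFSET = 2.0  # Å from Cα
CONTACT_THRESHOLD = 8.0  # Å, pseudo-Cβ distance
DEGENERATE_TOL = 1e-6  # Å; below this the Cα sits on the C1–C3 line


@dataclass(frozen=True)
class Contact:
    """A residue pair (i < j, 1-based) with a confidence score.

    Higher scores are more confident. For structure-derived contacts the
    score is the negated pseudo-Cβ distance so shorter distances rank first.
    """

    i: int
    j: int
    score: float

    def __post_init__(self) -> None:
        if not (1 <= self.i < self.j):
            raise ValueError(f"need 1 <= i < j, got ({self.i}, {self.j})")
        if not np.isfinite(self.score):
            raise ValueError(f"non-finite score for pair ({self.i}, {self.j})")

    @property
    def separation(self) -> int:
        return self.j - self.i


@dataclass
class ContactList:
    """Ranked contacts for one chain of known length.

    Contacts are kept sorted by descending score (ties by (i, j)); duplicate
    (i, j) pairs are rejected.
    """

    length: int
    contacts: list[Contact] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("chain length must be >= 1")
        seen = set()
        for c in self.contacts:
            if c.j > self.length:
                raise ValueError(f"contact ({c.i}, {c.j}) exceeds chain length {self.length}")
            if (c.i, c.j) in seen:
                raise ValueError(f"duplicate contact pair ({c.i}, {c.j})")
            seen.add((c.i, c.j))
        self.contacts = sorted(self.contacts, key=lambda c: (-c.score, c.i, c.j))

    def __len__(self) -> int:
        return len(self.contacts)

    def __iter__(self):
        return iter(self.contacts)

    def pairs(self) -> np.ndarray:
        """(n, 2) int array of (i, j) pairs in rank order."""
        if not self.contacts:
            return np.empty((0, 2), dtype=np.int64)
        return np.array([(c.i, c.j) for c in self.contacts], dtype=np.int64)


def read_rr(source: str | Path | IO[str], length: int | None = None) -> ContactList:
    """Read a CASP RR contact file.

    The format is optional free-text headers (PFRMAT/TARGET/MODEL/...), optional
    sequence lines (letters only, possibly wrapped), then whitespace-separated
    records ``i j dmin dmax prob``. Chain length is taken from the concatenated
    sequence lines when present, overridden by ``length`` if given, else the
    largest j seen. Records with i >= j are normalized by swapping (warning);
    duplicate pairs keep the higher score (warning).
    """
    close = False
    if isinstance(source, (str, Path)):
        stream: IO[str] = open(source)
        close = True
    else:
        stream = source
    try:
        seq_parts: list[str] = []
        best: dict[tuple[int, int], float] = {}
        for lineno, raw in enumerate(stream, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            upper = line.upper()
            if upper.startswith(("PFRMAT", "TARGET", "AUTHOR", "METHOD", "MODEL", "REMARK", "END")):
                continue
            fields = line.split()
            if len(fields) == 1 and fields[0].isalpha():
                seq_parts.append(fields[0])
                continue
            if len(fields) < 5:
                raise ValueError(f"line {lineno}: malformed RR record {line!r}")
            try:
                i, j = int(fields[0]), int(fields[1])
                score = float(fields[4])
            except ValueError:
                raise ValueError(f"line {lineno}: malformed RR record {line!r}") from None
            if i == j:
                raise ValueError(f"line {lineno}: self-contact ({i}, {j})")
            if i > j:
                logger.warning("line %d: residue order swapped for pair (%d, %d)", lineno, i, j)
                i, j = j, i
            if (i, j) in best:
                logger.warning("line %d: duplicate pair (%d, %d); keeping higher score", lineno, i, j)
                best[(i, j)] = max(best[(i, j)], score)
            else:
                best[(i, j)] = score
    finally:
        if close:
            stream.close()

    if length is None:
        if seq_parts:
            length = len("".join(seq_parts))
        elif best:
            length = max(j for _, j in best)
        else:
            raise ValueError("cannot infer chain length: no sequence and no contacts")
    contacts = [Contact(i, j, s) for (i, j), s in best.items()]
    return ContactList(length, contacts)


def write_rr(cl: ContactList, dest: str | Path | IO[str], sequence: str | None = None) -> None:
    """Write contacts as RR records ``i j 0 8 score`` (rank order preserved)."""
    close = False
    if isinstance(dest, (str, Path)):
        stream: IO[str] = open(dest, "w")
        close = True
    else:
        stream = dest
    try:
        if sequence is not None:
            for k in range(0, len(sequence), 50):
                stream.write(sequence[k : k + 50] + "\n")
        for c in cl:
            stream.write(f"{c.i} {c.j} 0 8 {c.score:.6g}\n")
    finally:
        if close:
            stream.close()


@dataclass
class ChainCoords:
    """Cα trace of one chain: (n, 3) coordinates in Å, residues 1..n.

    Residues are renumbered sequentially over observed Cα atoms on read (PDB
    author numbering, including insertion codes, collapses to sequential
    order); gaps in the source numbering are logged.
    """

    ca: np.ndarray

    def __post_init__(self) -> None:
        self.ca = np.asarray(self.ca, dtype=float)
        if self.ca.ndim != 2 or self.ca.shape[1] != 3:
            raise ValueError("coordinates must have shape (n, 3)")
        if not np.isfinite(self.ca).all():
            raise ValueError("non-finite coordinates")

    def __len__(self) -> int:
        return self.ca.shape[0]

    def __getitem__(self, residue: int) -> np.ndarray:
        """Cα position of 1-based residue index."""
        if not (1 <= residue <= len(self)):
            raise IndexError(f"residue {residue} outside 1..{len(self)}")
        return self.ca[residue - 1]


def read_ca_coords(path: str | Path, chain: str | None = None) -> ChainCoords:
    """Read Cα coordinates for one chain from a PDB (or mmCIF) file via gemmi.

    ``chain`` selects the chain by ID; default is the first chain of the
    first model. Residues lacking a Cα atom are skipped and reported.
    """
    import gemmi

    structure = gemmi.read_structure(str(path))
    structure.setup_entities()
    if len(structure) == 0:
        raise ValueError(f"{path}: no models")
    model = structure[0]
    if chain is None:
        gchain = model[0]
    else:
        gchain = model.find_chain(chain)
        if gchain is None:
            raise ValueError(f"{path}: chain {chain!r} not found")
    coords = []
    missing = []
    prev_seqid = None
    gap_after = []
    for res in gchain:
        atom = res.find_atom("CA", "*")
        if atom is None:
            missing.append(str(res.seqid))
            continue
        if prev_seqid is not None and res.seqid.num > prev_seqid + 1:
            gap_after.append(prev_seqid)
        prev_seqid = res.seqid.num
        coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
    if missing:
        logger.warning("%s chain %s: %d residues without CA skipped", path, gchain.name, len(missing))
    if gap_after:
        logger.warning("%s chain %s: numbering gaps after author residues %s; chain renumbered 1..%d",
                       path, gchain.name, gap_after, len(coords))
    if not coords:
        raise ValueError(f"{path}: no CA atoms in chain {gchain.name}")
    return ChainCoords(np.array(coords))


def write_ca_pdb(coords: ChainCoords, dest: str | Path, chain_id: str = "A") -> None:
    """Write a Cα-only PDB file (poly-alanine) for the given trace."""
    lines = []
    for r in range(1, len(coords) + 1):
        x, y, z = coords[r]
        lines.append(
            f"ATOM  {r:5d}  CA  ALA {chain_id}{r:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        )
    lines.append("END")
    Path(dest).write_text("\n".join(lines) + "\n")


def pseudo_cbeta(coords: ChainCoords) -> np.ndarray:
    """Pseudo-Cβ positions for every residue, shape (n, 3).

    For each interior residue r the flanking Cα atoms define a line; B is the
    orthogonal projection of Cα(r) onto it and the pseudo-Cβ is placed 2 Å
    from Cα(r) along B→Cα(r), i.e. away from the local backbone axis.
    Terminal residues, and residues whose Cα lies on the flanking line
    (collinear triple) or whose flanking Cαs coincide, fall back to the Cα
    itself.
    """
    n = len(coords)
    if n < 3:
        raise ValueError("pseudo-Cbeta derivation needs at least 3 residues")
    ca = coords.ca
    cb = ca.copy()  # termini and degenerate cases fall back to Cα
    c1, c2, c3 = ca[:-2], ca[1:-1], ca[2:]
    axis = c3 - c1
    axis_len2 = np.einsum("ij,ij->i", axis, axis)
    safe = axis_len2 > DEGENERATE_TOL**2
    t = np.zeros(len(c2))
    t[safe] = np.einsum("ij,ij->i", (c2 - c1)[safe], axis[safe]) / axis_len2[safe]
    b = c1 + t[:, None] * axis  # projection of C2 onto the C1–C3 line
    away = c2 - b
    dist = np.linalg.norm(away, axis=1)
    ok = safe & (dist > DEGENERATE_TOL)
    n_bad = int((~ok).sum())
    if n_bad:
        logger.warning("%d interior residues degenerate (collinear backbone); using Cα", n_bad)
    cb[1:-1][ok] = c2[ok] + PSEUDO_CB_OFFSET * away[ok] / dist[ok, None]
    return cb


def derive_structure_contacts(coords: ChainCoords, threshold: float = CONTACT_THRESHOLD) -> ContactList:
    """All residue pairs whose pseudo-Cβ distance is at most ``threshold`` Å.

    Scores are the negated distance, so the ranking places the shortest
    (most contact-like) distances first.
    """
    cb = pseudo_cbeta(coords)
    diff = cb[:, None, :] - cb[None, :, :]
    dmat = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    ii, jj = np.triu_indices(len(coords), k=1)
    keep = dmat[ii, jj] <= threshold
    contacts = [
        Contact(int(i) + 1, int(j) + 1, -float(d))
        for i, j, d in zip(ii[keep], jj[keep], dmat[ii, jj][keep])
    ]
    return ContactList(len(coords), contacts)


def filter_contacts(cl: ContactList, min_sep: int = 5, top_n: int = 1000) -> ContactList:
    """Drop short-range pairs (j - i < min_sep), then keep the top_n by score.

    Rank order is preserved; fewer than top_n survivors are all retained.
    """
    if top_n <= 0:
        raise ValueError("top_n must be positive")
    kept = [c for c in cl if c.separation >= min_sep]
    return ContactList(cl.length, kept[:top_n])
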