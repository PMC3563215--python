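"""Seeded synthetic fixtures: contact maps with domain structure, ideal-helix
coordinates, length-model training tables and alignment endpoint samples.

The contact simulator encodes the structural premiss the contact-based
predictors rely on: residues within the same compact domain are far more
likely to be in contact than residues in different domains, with intra-domain
contact probability decaying with sequence separation, and a fraction of the
reported list being random noise pairs. True contacts draw high scores
(Beta(5, 2) by default) and noise pairs low scores (Beta(2, 5)), so score
ranking is informative but imperfect — the two distributions overlap.

Every generator is a pure function of its arguments and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .contacts import ChainCoords, Contact, ContactList
from .domains import DomainAnnotation, Segment

__all__ = [
    "SimSpec",
    "generate_multidomain_contacts",
    "generate_helix_coordinates",
    "generate_length_training_set",
    "generate_endpoint_samples",
    "sample_benchmark_fixture",
]

MIN_SEQ_SEP = 5  # generated contacts respect the predictor's separation filter

# ideal α-helix Cα trace parameters
HELIX_RADIUS = 2.3  # Å
HELIX_RISE = 1.5  # Å per residue
HELIX_TWIST = 100.0  # degrees per residue


@dataclass(frozen=True)
class SimSpec:
    """Parameters of one simulated multidomain contact list.

    p_intra / p_inter are per-pair inclusion probabilities for same-domain /
    cross-domain pairs; same-domain pairs are further damped by
    exp(−(j−i)/decay). noise_frac is the fraction of the final list drawn
    uniformly at random from unused pairs. Score distributions are Beta:
    true contacts ~ Beta(*score_true*), noise ~ Beta(*score_noise*).
    """

    domain_lengths: tuple[int, ...]
    p_intra: float = 0.08
    p_inter: float = 0.002
    decay: float = 100.0
    noise_frac: float = 0.2
    score_true: tuple[float, float] = (5.0, 2.0)
    score_noise: tuple[float, float] = (2.0, 5.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.domain_lengths:
            raise ValueError("at least one domain required")
        if any(d < 20 for d in self.domain_lengths):
            raise ValueError("domain lengths must be >= 20 residues")
        if not (0 <= self.p_inter < self.p_intra <= 1):
            raise ValueError("need 0 <= p_inter < p_intra <= 1")
        if not (0 <= self.noise_frac < 1):
            raise ValueError("noise_frac must lie in [0, 1)")
        if self.decay <= 0:
            raise ValueError("decay must be positive")

    @property
    def length(self) -> int:
        return int(sum(self.domain_lengths))

    @property
    def boundaries(self) -> list[int]:
        """First residue of each domain after the first."""
        cuts = np.cumsum(self.domain_lengths)[:-1] + 1
        return [int(c) for c in cuts]

    def annotation(self) -> DomainAnnotation:
        starts = [1] + self.boundaries
        ends = list(np.cumsum(self.domain_lengths))
        return DomainAnnotation(self.length, [[Segment(s, int(e))] for s, e in zip(starts, ends)])


def generate_multidomain_contacts(spec: SimSpec):
    """Simulate a ranked contact list with known domain structure.

    Returns (ContactList, true boundary positions, true DomainAnnotation).
    All generated pairs respect the minimum sequence separation of 5; with
    p_inter = 0 and noise_frac = 0 no contact crosses a domain boundary.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.length
    domain_of = np.repeat(np.arange(len(spec.domain_lengths)), spec.domain_lengths)

    ii, jj = np.triu_indices(L, k=MIN_SEQ_SEP)
    same = domain_of[ii] == domain_of[jj]
    sep = (jj - ii).astype(float)
    prob = np.where(same, spec.p_intra * np.exp(-sep / spec.decay), spec.p_inter)
    draw = rng.random(len(ii))
    is_true = draw < prob

    true_i, true_j = ii[is_true] + 1, jj[is_true] + 1
    n_true = len(true_i)
    if n_true == 0:
        raise ValueError("spec produced no true contacts; raise p_intra or domain sizes")

    n_noise = int(round(n_true * spec.noise_frac / (1.0 - spec.noise_frac)))
    unused = np.flatnonzero(~is_true)
    if n_noise > len(unused):
        raise ValueError("not enough candidate pairs for the requested noise fraction")
    noise_idx = rng.choice(unused, size=n_noise, replace=False) if n_noise else np.array([], dtype=int)
    noise_i, noise_j = ii[noise_idx] + 1, jj[noise_idx] + 1

    scores_true = rng.beta(*spec.score_true, size=n_true)
    scores_noise = rng.beta(*spec.score_noise, size=n_noise)
    contacts = [
        Contact(int(a), int(b), float(s))
        for a, b, s in zip(
            np.concatenate([true_i, noise_i]),
            np.concatenate([true_j, noise_j]),
            np.concatenate([scores_true, scores_noise]),
        )
    ]
    return ContactList(L, contacts), spec.boundaries, spec.annotation()


def generate_helix_coordinates(n: int) -> ChainCoords:
    """Ideal α-helix Cα trace: radius 2.3 Å, rise 1.5 Å and 100° twist per
    residue. Deterministic; consecutive Cα–Cα distances are ≈ 3.8 Å."""
    if n < 3:
        raise ValueError("helix needs at least 3 residues")
    t = np.arange(n)
    angle = np.deg2rad(HELIX_TWIST) * t
    coords = np.column_stack([
        HELIX_RADIUS * np.cos(angle),
        HELIX_RADIUS * np.sin(angle),
        HELIX_RISE * t,
    ])
    return ChainCoords(coords)


DEFAULT_PRIORS = (0.5, 0.3, 0.15, 0.05)
# per-domain length scale of the lognormal chain-length model (≈ a CATH-like
# median domain size of 130 residues)
DOMAIN_LENGTH_MEDIAN = 130.0
LOG_LENGTH_SD = 0.25


def generate_length_training_set(
    n: int,
    priors=DEFAULT_PRIORS,
    seed: int = 0,
    boundary_jitter: float = 0.06,
    length_median: float = DOMAIN_LENGTH_MEDIAN,
    log_sd: float = LOG_LENGTH_SD,
):
    """Training records (L, n_domains, boundary positions) for the naive
    predictor.

    Class N is drawn from ``priors`` over {1, 2, 3, 4+} (the 4+ class
    realizes 4 or 5 domains); chain length is lognormal with median
    N·length_median; boundaries sit at uniform spacing k·L/N plus Gaussian
    jitter of sd = boundary_jitter·L, clamped strictly inside (1, L).
    """
    priors = np.asarray(priors, dtype=float)
    if abs(priors.sum() - 1.0) > 1e-9:
        raise ValueError("priors must sum to 1")
    rng = np.random.default_rng(seed)
    records = []
    for _ in range(n):
        cls = int(rng.choice(4, p=priors)) + 1
        n_dom = cls if cls < 4 else int(rng.integers(4, 6))
        L = max(40 * n_dom, int(round(float(rng.lognormal(math.log(length_median * n_dom), log_sd)))))
        boundaries = []
        for k in range(1, n_dom):
            p = int(round(k * L / n_dom + rng.normal(0.0, boundary_jitter * L)))
            boundaries.append(min(L - 1, max(2, p)))
        boundaries = sorted(set(boundaries))
        records.append((L, n_dom, boundaries))
    return records


def generate_endpoint_samples(
    boundaries: list[int], L: int, n: int, jitter_sd: float = 5.0, seed: int = 0
):
    """Alignment endpoint pairs clustering around domain termini.

    Each sample picks one domain (implied by the boundary list) uniformly and
    jitters its (start, end) with Gaussian noise of the given sd, clipping to
    [1, L]. With jitter_sd = 0 every endpoint falls exactly on a terminus.
    """
    for b in boundaries:
        if not (1 < b <= L):
            raise ValueError(f"boundary {b} invalid for L={L}")
    rng = np.random.default_rng(seed)
    starts = [1] + sorted(boundaries)
    ends = [b - 1 for b in sorted(boundaries)] + [L]
    pairs = []
    for _ in range(n):
        d = int(rng.integers(0, len(starts)))
        s = int(np.clip(round(starts[d] + rng.normal(0.0, jitter_sd)), 1, L))
        e = int(np.clip(round(ends[d] + rng.normal(0.0, jitter_sd)), 1, L))
        if s > e:
            s, e = e, s
        pairs.append((s, e))
    return pairs


# multidomain benchmark composition: 2-domain chains dominate real domain
# databases; 3- and 4-domain chains are progressively rarer
DOMAIN_COUNT_WEIGHTS = {2: 0.70, 3: 0.20, 4: 0.10}
DOMAIN_SIZE_RANGE = (80, 180)  # residues, typical globular domain sizes


def sample_benchmark_fixture(rng: np.random.Generator, n_domains: int | None = None) -> SimSpec:
    """Draw one multidomain benchmark protein spec.

    The domain count is 2–4 with weights 0.70/0.20/0.10 (unless given), each
    domain a uniform 80–180 residues, default contact statistics, child seed
    drawn from ``rng``.
    """
    if n_domains is None:
        counts = sorted(DOMAIN_COUNT_WEIGHTS)
        probs = [DOMAIN_COUNT_WEIGHTS[c] for c in counts]
        n_domains = int(rng.choice(counts, p=probs))
    lo, hi = DOMAIN_SIZE_RANGE
    lengths = tuple(int(x) for x in rng.integers(lo, hi + 1, size=n_domains))
    return SimSpec(domain_lengths=lengths, seed=int(rng.integers(0, 2**31 - 1)))
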