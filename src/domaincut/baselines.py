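"""Baseline domain predictors: length-based Bayesian and homology endpoints.

The naive (length-based) predictor knows nothing about a chain except its
length L. From a training table of (chain length, domain count, boundary
positions) it fits, per domain-count class N in {1, 2, 3, 4+}, a Gaussian
KDE over chain lengths f_N(L) and a length-independent boundary-position
profile over sequences rescaled to 1000 cells. Prediction combines the
posterior P(N|L) ∝ f_N(L)·P(N) with the class boundary profiles rescaled to
the query length, and cuts wherever the mixed profile peaks.

The homology predictor consumes alignment endpoint tables (from a profile
HMM search against a domain-family library, performed upstream): start/end
positions are accumulated into a per-residue profile, smoothed by repeated
moving-window averaging, and boundaries placed at the tallest peaks subject
to a minimum spacing of 60 residues from the termini and from each other.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.stats import gaussian_kde

from .domains import DomainAnnotation
from .kde import SLOPE_WINDOW, find_peaks

logger = logging.getLogger(__name__)

__all__ = [
    "LengthModel",
    "fit_length_model",
    "posterior_ndomains",
    "rescale_profile",
    "predict_naive",
    "assemble_endpoint_profile",
    "smooth_by_averaging",
    "predict_from_endpoints",
    "read_endpoint_tsv",
]

N_CLASSES = (1, 2, 3, 4)  # class 4 means "4 or more domains"
PROFILE_CELLS = 1000
MIN_BOUNDARY_DIST = 60  # residues, homology exclusion rule


@dataclass
class LengthModel:
    """Fitted priors, per-class length KDEs and boundary-position profiles.

    priors: P(N) for N in {1, 2, 3, 4+}. length_samples holds the training
    chain lengths per class (the KDE support); bandwidths are Silverman's
    rule, recorded per class. boundary_profiles is a (4, 1000) array; each
    row sums to 1, except a class with no observed boundaries (always the
    single-domain class) whose row is identically zero.
    """

    priors: np.ndarray
    length_samples: dict[int, np.ndarray]
    boundary_profiles: np.ndarray
    bandwidths: dict[int, float] = field(default_factory=dict)
    _kdes: dict[int, gaussian_kde] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.priors = np.asarray(self.priors, dtype=float)
        if abs(self.priors.sum() - 1.0) > 1e-9:
            raise ValueError("class priors must sum to 1")
        for idx, n in enumerate(N_CLASSES):
            row_sum = self.boundary_profiles[idx].sum()
            if not (abs(row_sum - 1.0) < 1e-9 or row_sum == 0.0):
                raise ValueError(f"boundary profile for class {n} must sum to 1 or be zero")
        for n in N_CLASSES:
            samples = np.asarray(self.length_samples[n], dtype=float)
            self.length_samples[n] = samples
            if len(samples) >= 2 and samples.std(ddof=1) > 0:
                kde = gaussian_kde(samples, bw_method="silverman")
                self._kdes[n] = kde
                self.bandwidths.setdefault(n, float(kde.factor * samples.std(ddof=1)))
            else:
                # degenerate class (one chain, or identical lengths): unit-width kernel
                self._kdes[n] = None
                self.bandwidths.setdefault(n, 1.0)

    def length_density(self, n: int, L: float) -> float:
        """f_N(L): Gaussian-KDE density of chain length within class n."""
        kde = self._kdes[n]
        if kde is None:
            h = self.bandwidths[n]
            z = (L - self.length_samples[n]) / h
            return float(np.mean(np.exp(-0.5 * z * z) / (h * np.sqrt(2 * np.pi))))
        return float(kde(L)[0])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "format": "domaincut-length-model",
            "version": 1,
            "priors": self.priors.tolist(),
            "length_samples": {str(n): self.length_samples[n].tolist() for n in N_CLASSES},
            "bandwidths": {str(n): self.bandwidths[n] for n in N_CLASSES},
            "boundary_profiles": self.boundary_profiles.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "LengthModel":
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != "domaincut-length-model":
            raise ValueError(f"{path}: not a length-model file")
        return cls(
            priors=np.array(payload["priors"]),
            length_samples={int(k): np.array(v) for k, v in payload["length_samples"].items()},
            boundary_profiles=np.array(payload["boundary_profiles"]),
            bandwidths={int(k): float(v) for k, v in payload["bandwidths"].items()},
        )


def _class_of(n_domains: int) -> int:
    return min(int(n_domains), 4)


def fit_length_model(training) -> LengthModel:
    """Fit a LengthModel from records of (L, n_domains, boundary positions).

    Class priors are the empirical class frequencies; chains with 4 or more
    domains pool into the 4+ class. Each boundary position p in a chain of
    length L maps to cell floor(1000·(p−1)/L) of the class profile; the
    accumulated histogram is KDE-smoothed (Gaussian kernel, Silverman
    bandwidth over the cell sample) and normalized. Raises if any class has
    no training chain.
    """
    records = list(training)
    by_class: dict[int, list] = {n: [] for n in N_CLASSES}
    for L, n_dom, boundaries in records:
        by_class[_class_of(n_dom)].append((int(L), list(boundaries)))
    empty = [n for n in N_CLASSES if not by_class[n]]
    if empty:
        raise ValueError(f"no training chains for domain-count class(es): {empty}")

    priors = np.array([len(by_class[n]) for n in N_CLASSES], dtype=float)
    priors /= priors.sum()
    length_samples = {n: np.array([L for L, _ in by_class[n]], dtype=float) for n in N_CLASSES}
    profiles = np.zeros((len(N_CLASSES), PROFILE_CELLS))
    for idx, n in enumerate(N_CLASSES):
        cells = []
        for L, boundaries in by_class[n]:
            for p in boundaries:
                if not (1 <= p <= L):
                    raise ValueError(f"boundary {p} outside chain of length {L}")
                cell = min(PROFILE_CELLS - 1, int(PROFILE_CELLS * (p - 1) / L))
                profiles[idx, cell] += 1.0
                cells.append(cell)
        if cells:
            # Gaussian-KDE smoothing of the accumulated histogram, Silverman
            # bandwidth from the cell sample (floor of 1 cell for degenerate
            # samples) — raw cell counts are far too spiky for peak detection
            h = _silverman_bandwidth(np.array(cells, dtype=float))
            profiles[idx] = gaussian_filter1d(profiles[idx], sigma=h, mode="constant")
            profiles[idx] /= profiles[idx].sum()
    return LengthModel(priors, length_samples, profiles)


def _silverman_bandwidth(sample: np.ndarray) -> float:
    m = len(sample)
    if m < 2:
        return 1.0
    sd = sample.std(ddof=1)
    iqr = np.subtract(*np.percentile(sample, [75, 25])) / 1.34
    spread = min(sd, iqr) if iqr > 0 else sd
    return max(1.0, 0.9 * spread * m ** (-0.2))


def posterior_ndomains(L: float, model: LengthModel) -> np.ndarray:
    """P(N|L) over the classes {1, 2, 3, 4+}: f_N(L)·P(N), normalized.

    If every class density vanishes at L (a length far outside all training
    data), the priors are returned with a warning.
    """
    if L < 1:
        raise ValueError("chain length must be >= 1")
    likes = np.array([model.length_density(n, L) for n in N_CLASSES])
    joint = likes * model.priors
    total = joint.sum()
    if total <= 0 or not np.isfinite(total):
        logger.warning("all class densities vanish at L=%s; falling back to priors", L)
        return model.priors.copy()
    return joint / total


def rescale_profile(cells: np.ndarray, L: int) -> np.ndarray:
    """Map a 1000-cell profile onto a chain of length L, conserving mass.

    Residue r covers the cell-axis interval [1000(r−1)/L, 1000r/L); each cell
    contributes to a residue in proportion to the overlap of its unit
    interval with the residue's interval (for L=100, residue 1 is exactly the
    sum of cells 0–9; for L=1000 the mapping is the identity).
    """
    cells = np.asarray(cells, dtype=float)
    n_cells = len(cells)
    if L < 1:
        raise ValueError("L must be >= 1")
    edges = n_cells * np.arange(L + 1, dtype=float) / L  # residue borders on the cell axis
    out = np.empty(L)
    for r in range(L):
        a, b = edges[r], edges[r + 1]
        lo, hi = int(np.floor(a)), min(int(np.ceil(b)), n_cells)
        k = np.arange(lo, hi)
        overlap = np.minimum(b, k + 1.0) - np.maximum(a, k.astype(float))
        out[r] = float(np.sum(cells[lo:hi] * np.clip(overlap, 0.0, None)))
    return out


def predict_naive(
    L: int, model: LengthModel, map_n: bool = False, w: int = SLOPE_WINDOW
) -> DomainAnnotation:
    """Length-only domain prediction.

    The boundary profile for the query is the posterior mixture
    Σ_N P(N|L) · rescale(b_N, L); with ``map_n`` True only the maximum
    a-posteriori class's profile is used instead. Cuts are placed at the
    peaks of this profile (windowed-slope sign changes); no peaks means a
    single-domain call.
    """
    post = posterior_ndomains(L, model)
    if map_n:
        idx = int(np.argmax(post))
        profile = post[idx] * rescale_profile(model.boundary_profiles[idx], L)
    else:
        profile = np.zeros(L)
        for idx in range(len(N_CLASSES)):
            if post[idx] > 0:
                profile += post[idx] * rescale_profile(model.boundary_profiles[idx], L)
    peaks = find_peaks(profile, w=w)
    return DomainAnnotation.from_cuts(L, peaks)


def assemble_endpoint_profile(endpoints, L: int) -> np.ndarray:
    """Per-residue counts of alignment starts and ends.

    counts[p−1] = #alignments starting at p + #alignments ending at p.
    Raises on endpoints outside 1..L or start > end, naming the record.
    """
    counts = np.zeros(L, dtype=float)
    for rec_no, (start, end) in enumerate(endpoints, start=1):
        if not (1 <= start <= end <= L):
            raise ValueError(f"endpoint record {rec_no}: ({start}, {end}) invalid for L={L}")
        counts[start - 1] += 1.0
        counts[end - 1] += 1.0
    return counts


def smooth_by_averaging(profile: np.ndarray, window: int = 5, iterations: int = 10) -> np.ndarray:
    """Repeated moving-average smoothing of an endpoint profile.

    Each iteration replaces every value by the mean of the (2·window + 1)
    positions around it, windows truncating at the chain ends. Repeated
    application flattens the profile; end truncation means total mass is
    preserved only approximately near the termini.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    values = np.asarray(profile, dtype=float).copy()
    L = len(values)
    # window sizes per position are fixed across iterations
    starts = np.maximum(0, np.arange(L) - window)
    stops = np.minimum(L, np.arange(L) + window + 1)
    widths = (stops - starts).astype(float)
    for _ in range(iterations):
        csum = np.concatenate([[0.0], np.cumsum(values)])
        values = (csum[stops] - csum[starts]) / widths
    return values


def predict_from_endpoints(
    profile: np.ndarray, min_dist: int = MIN_BOUNDARY_DIST, w: int = SLOPE_WINDOW
) -> DomainAnnotation:
    """Boundary prediction from a smoothed endpoint profile.

    Candidate peaks are taken in decreasing height order (ties toward the
    lower position) and accepted greedily when at least ``min_dist`` residues
    from both termini and from every already-accepted boundary. No
    acceptable peak yields a single-domain call; chains shorter than
    2·min_dist + 1 can never host a boundary.
    """
    values = np.asarray(profile, dtype=float)
    L = len(values)
    peaks = find_peaks(values, w=w)
    order = sorted(peaks, key=lambda p: (-values[p - 1], p))
    accepted: list[int] = []
    for p in order:
        if p - 1 < min_dist or L - p < min_dist:
            continue
        if any(abs(p - q) < min_dist for q in accepted):
            continue
        accepted.append(p)
    return DomainAnnotation.from_cuts(L, sorted(accepted))


def read_endpoint_tsv(path: str | Path, target_id: str | None = None):
    """Read alignment endpoints from a TSV with columns
    target_id, ali_start, ali_end, bitscore (header optional).

    Returns a list of (start, end) pairs, filtered to ``target_id`` if given.
    """
    pairs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path} line {lineno}: expected >= 3 tab-separated columns")
            if lineno == 1 and not fields[1].lstrip("-").isdigit():
                continue  # header row
            if target_id is not None and fields[0] != target_id:
                continue
            pairs.append((int(fields[1]), int(fields[2])))
    return pairs
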