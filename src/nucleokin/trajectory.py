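"""Pair-structure metrics from particle trajectories.

Native implementations of the radial distribution function g(r) (periodic
orthorhombic boxes, minimum-image convention), coordination numbers (direct
counting or RDF integration), the most-probable and first-approach
separation distances, and a cation-anion pairing classification
(contact / solvent-shared / solvent-separated) from the first-peak position.

Species are selected by label string (e.g. ``Ca``, ``S_sulfate``,
``O_water``); no chemical topology is inferred.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError, ValidationError

DEFAULT_BIN_WIDTH = 0.1      # Angstrom
DEFAULT_CONTACT_MAX = 3.2    # Angstrom; upper bound for contact ion pairs
DEFAULT_SHARED_MAX = 5.6     # Angstrom; upper bound for solvent-shared pairs


@dataclass(frozen=True)
class TrajectoryFrame:
    """One snapshot: Nx3 coordinates (Angstrom), per-particle labels, box."""

    positions: np.ndarray
    labels: tuple[str, ...]
    box: tuple[float, float, float]
    periodic: bool = True

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValidationError("positions must be an (N, 3) array")
        if len(self.labels) != pos.shape[0]:
            raise ValidationError("labels length must equal particle count")
        if any(b <= 0 for b in self.box):
            raise ValidationError("box lengths must be > 0")
        object.__setattr__(self, "positions", pos)

    def select(self, label: str) -> np.ndarray:
        idx = [i for i, lab in enumerate(self.labels) if lab == label]
        return self.positions[idx]


@dataclass(frozen=True)
class RDFResult:
    """Binned pair correlation g(r) with the metadata needed to integrate it."""

    r_centers: np.ndarray
    g: np.ndarray
    bin_width: float
    density_b: float    # effective particles/A^3 of species B used in normalization
    n_frames: int

    def __post_init__(self):
        if np.any(np.asarray(self.g) < 0):
            raise ValidationError("g(r) must be non-negative")


@dataclass(frozen=True)
class PairingClassification:
    """Ion-pairing category from the first-peak position of an RDF."""

    category: str               # contact | solvent-shared | solvent-separated
    first_peak_r: float
    cutoffs: tuple[float, float]


def _pair_distances(pos_a: np.ndarray, pos_b: np.ndarray,
                    box: np.ndarray, periodic: bool, like: bool) -> np.ndarray:
    """Flat array of A-B (minimum-image) distances; self-pairs excluded."""
    diff = pos_a[:, None, :] - pos_b[None, :, :]
    if periodic:
        diff -= box * np.round(diff / box)
    r = np.sqrt(np.sum(diff * diff, axis=-1))
    if like:
        n = r.shape[0]
        mask = ~np.eye(n, dtype=bool)
        return r[mask]
    return r.ravel()


def radial_distribution(
    frames,
    species_a: str,
    species_b: str,
    bin_width: float = DEFAULT_BIN_WIDTH,
    r_max: float | None = None,
) -> RDFResult:
    """Histogram A-B pair distances, normalized to an ideal gas at density
    rho_B = N_B_eff / V (N_B - 1 for like pairs, the per-reference-particle
    convention), so that an uncorrelated system gives g(r) = 1.
    """
    frames = list(frames)
    if not frames:
        raise ValidationError("need at least one frame")
    box = np.asarray(frames[0].box, dtype=float)
    periodic = frames[0].periodic
    half_min = float(np.min(box)) / 2.0
    if r_max is None:
        r_max = half_min
    if periodic and r_max > half_min + 1e-12:
        raise ValidationError(
            f"r_max = {r_max} exceeds half the smallest box edge ({half_min}); "
            "the minimum-image convention breaks beyond that"
        )
    like = species_a == species_b
    n_bins = int(np.ceil(r_max / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    hist = np.zeros(n_bins)
    n_a_total = 0
    density_sum = 0.0
    for frame in frames:
        pos_a = frame.select(species_a)
        pos_b = frame.select(species_b)
        if pos_a.size == 0 or pos_b.size == 0:
            raise ValidationError(
                f"empty species selection ({species_a!r} or {species_b!r})"
            )
        r = _pair_distances(pos_a, pos_b, box, periodic, like)
        hist += np.histogram(r, bins=edges)[0]
        n_a_total += pos_a.shape[0]
        n_b_eff = pos_b.shape[0] - (1 if like else 0)
        density_sum += n_b_eff / float(np.prod(box))
    density_b = density_sum / len(frames)
    shell_volumes = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    ideal = n_a_total * density_b * shell_volumes
    with np.errstate(invalid="ignore", divide="ignore"):
        g = np.where(ideal > 0, hist / ideal, 0.0)
    centers = 0.5 * (edges[1:] + edges[:-1])
    return RDFResult(r_centers=centers, g=g, bin_width=bin_width,
                     density_b=density_b, n_frames=len(frames))


def coordination_number(
    frames,
    species_a: str,
    species_b: str,
    r_cut: float,
    method: str = "direct",
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> float:
    """Mean number of B particles within r_cut of an A particle.

    ``direct`` counts neighbours frame by frame; ``rdf`` integrates
    4 pi rho_B int_0^rcut g(r) r^2 dr on the binned histogram.  The two
    agree within binning tolerance on well-sampled data.
    """
    if r_cut <= 0:
        raise DomainError("r_cut must be > 0")
    if method == "rdf":
        rdf = radial_distribution(frames, species_a, species_b,
                                  bin_width=bin_width, r_max=r_cut)
        return coordination_from_rdf(rdf, r_cut)
    if method != "direct":
        raise ValidationError(f"unknown coordination method {method!r}")
    frames = list(frames)
    if not frames:
        raise ValidationError("need at least one frame")
    box = np.asarray(frames[0].box, dtype=float)
    like = species_a == species_b
    total, n_a = 0.0, 0
    for frame in frames:
        pos_a = frame.select(species_a)
        pos_b = frame.select(species_b)
        if pos_a.size == 0 or pos_b.size == 0:
            raise ValidationError("empty species selection")
        r = _pair_distances(pos_a, pos_b, box, frame.periodic, like)
        total += np.count_nonzero(r <= r_cut)
        n_a += pos_a.shape[0]
    return total / n_a


def coordination_from_rdf(rdf: RDFResult, r_cut: float) -> float:
    """Integrate the binned g(r): N(r_cut) = sum_bins 4 pi rho r^2 dr g."""
    keep = rdf.r_centers <= r_cut
    shell = 4.0 * np.pi * rdf.r_centers[keep] ** 2 * rdf.bin_width
    return float(np.sum(rdf.g[keep] * shell) * rdf.density_b)


def most_probable_distance(rdf: RDFResult) -> float:
    """Bin center of the global maximum of g(r); ties go to smaller r."""
    if not np.any(rdf.g > 0):
        raise DomainError("g(r) is identically zero")
    return float(rdf.r_centers[int(np.argmax(rdf.g))])


def first_approach_distance(rdf: RDFResult, g_threshold: float = 0.0) -> float:
    """Smallest bin center where g(r) exceeds the threshold (noise floor)."""
    above = np.nonzero(rdf.g > g_threshold)[0]
    if above.size == 0:
        raise DomainError(f"no bin has g > {g_threshold}")
    return float(rdf.r_centers[above[0]])


def classify_ion_pairing(
    rdf: RDFResult,
    contact_max: float = DEFAULT_CONTACT_MAX,
    shared_max: float = DEFAULT_SHARED_MAX,
) -> PairingClassification:
    """Classify by first-peak position with closed upper bounds.

    <= contact_max -> contact; <= shared_max -> solvent-shared (one water
    layer between the ions); else solvent-separated.  The cutoffs are
    configurable heuristics.
    """
    if contact_max >= shared_max:
        raise ValidationError("contact_max must be < shared_max")
    peak = most_probable_distance(rdf)
    if peak <= contact_max:
        category = "contact"
    elif peak <= shared_max:
        category = "solvent-shared"
    else:
        category = "solvent-separated"
    return PairingClassification(category=category, first_peak_r=peak,
                                 cutoffs=(contact_max, shared_max))
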