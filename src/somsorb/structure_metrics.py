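"""Structural and energetic descriptors of periodic particle configurations.

Implements the trajectory-level analysis toolbox: radial distribution
functions under the minimum-image convention, Kirkwood–Buff integrals and
the preferential-solvation coefficient built on them, a geometric
hydrogen-bond criterion, Shrake–Rupley solvent-accessible surface area with
carbon/heteroatom partitioning, and pairwise non-bonded interaction energies
with a reaction-field electrostatic correction.

All lengths are nm, energies kJ/mol, charges in elementary charge units.
Boxes are rectangular and periodic in all three directions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .constants import (
    COULOMB_KJ_NM_PER_MOL_E2,
    DEFAULT_CUTOFF,
    DEFAULT_EPS_RF,
)
from .errors import InvalidInputError

__all__ = [
    "Frame",
    "RdfProfile",
    "KbResult",
    "HBondCriterion",
    "SasaResult",
    "select",
    "minimum_image",
    "radial_distribution",
    "kb_integral",
    "heavy_atom_fractions",
    "preferential_solvation",
    "hydrogen_bonds",
    "sasa",
    "pair_interaction_energy",
]

ELEMENT_CLASSES = ("carbon", "heteroatom", "hydrogen")


@dataclass
class Frame:
    """One periodic configuration with per-particle annotations.

    ``species`` labels the molecular role (sorbate / LHA / water / calcium);
    ``element_class`` distinguishes carbon, heteroatom and hydrogen sites in
    the united-atom convention (aliphatic CHn counts as one carbon site).
    Charges, Lennard-Jones C6/C12 parameters and SASA radii are optional and
    only required by the operations that use them.
    """

    coordinates: np.ndarray
    box: np.ndarray
    species: np.ndarray
    element_class: np.ndarray
    charge: np.ndarray | None = None
    lj_c6: np.ndarray | None = None
    lj_c12: np.ndarray | None = None
    radius: np.ndarray | None = None
    names: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        self.species = np.asarray(self.species)
        self.element_class = np.asarray(self.element_class)
        n = self.n_atoms
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise InvalidInputError("coordinates must have shape (N, 3)")
        if not np.all(np.isfinite(self.coordinates)):
            raise InvalidInputError("coordinates must be finite")
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise InvalidInputError("box must be three positive edge lengths")
        if self.species.shape != (n,) or self.element_class.shape != (n,):
            raise InvalidInputError("species/element_class must label every particle")
        bad = set(np.unique(self.element_class)) - set(ELEMENT_CLASSES)
        if bad:
            raise InvalidInputError(f"unknown element classes: {sorted(bad)}")
        for attr in ("charge", "lj_c6", "lj_c12", "radius"):
            v = getattr(self, attr)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != (n,):
                    raise InvalidInputError(f"{attr} must have one value per particle")
                setattr(self, attr, v)

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[0]

    @property
    def volume(self) -> float:
        return float(np.prod(self.box))


Trajectory = Sequence[Frame]


def select(
    frame: Frame,
    species: str | Sequence[str] | None = None,
    element_class: str | Sequence[str] | None = None,
    heavy_only: bool = False,
) -> np.ndarray:
    """Indices of particles matching species / element-class filters."""
    mask = np.ones(frame.n_atoms, dtype=bool)
    if species is not None:
        wanted = {species} if isinstance(species, str) else set(species)
        mask &= np.isin(frame.species, list(wanted))
    if element_class is not None:
        wanted = (
            {element_class} if isinstance(element_class, str) else set(element_class)
        )
        mask &= np.isin(frame.element_class, list(wanted))
    if heavy_only:
        mask &= frame.element_class != "hydrogen"
    return np.flatnonzero(mask)


def minimum_image(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap displacement vectors into the central image of a rectangular box."""
    return d - box * np.round(d / box)


@dataclass
class RdfProfile:
    """Radial distribution function g(r) on equally spaced bins."""

    bin_centers: np.ndarray
    g: np.ndarray
    pair: tuple[str, str] = ("A", "B")
    bin_width: float = 0.0
    n_frames: int = 1

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        if self.bin_centers.shape != self.g.shape:
            raise InvalidInputError("bin_centers and g must align")
        if np.any(self.g < 0):
            raise InvalidInputError("g(r) must be non-negative")


@dataclass(frozen=True)
class KbResult:
    """Kirkwood–Buff integral G (nm³) up to a spherical boundary."""

    G: float
    upper_boundary: float
    starred: bool = False


@dataclass(frozen=True)
class HBondCriterion:
    """Geometric hydrogen-bond criterion: acceptor–hydrogen distance at most
    ``max_ha_distance`` (nm) and D–H···A angle at least ``min_donor_angle``
    degrees; both boundaries inclusive."""

    max_ha_distance: float = 0.25
    min_donor_angle: float = 135.0

    def __post_init__(self) -> None:
        if self.max_ha_distance <= 0:
            raise InvalidInputError("H···A distance bound must be positive")
        if not (0 < self.min_donor_angle <= 180):
            raise InvalidInputError("donor angle bound must be in (0, 180]")


@dataclass(frozen=True)
class SasaResult:
    """Solvent-accessible surface area (nm²) split by element class."""

    total: float
    carbon_fraction: float
    heteroatom_fraction: float


def _pair_distances_chunked(
    xa: np.ndarray, xb: np.ndarray, box: np.ndarray, chunk: int = 256
) -> Iterable[np.ndarray]:
    for start in range(0, xa.shape[0], chunk):
        d = xb[None, :, :] - xa[start : start + chunk, None, :]
        d = minimum_image(d, box)
        yield start, np.sqrt(np.einsum("ijk,ijk->ij", d, d))


def radial_distribution(
    traj: Trajectory | Frame,
    selection_a: np.ndarray,
    selection_b: np.ndarray,
    bin_width: float = 0.02,
    r_max: float = 1.5,
) -> RdfProfile:
    """g(r) between two particle selections, averaged over frames.

    Shell counts use the minimum-image convention and are normalized by the
    ideal-gas expectation n_B/V per frame; self-pairs (shared indices) are
    excluded.  ``r_max`` may not exceed half the smallest box edge, where the
    minimum-image distance ceases to be unique.
    """
    frames = [traj] if isinstance(traj, Frame) else list(traj)
    if not frames:
        raise InvalidInputError("empty trajectory")
    sel_a = np.asarray(selection_a, dtype=int)
    sel_b = np.asarray(selection_b, dtype=int)
    if sel_a.size == 0 or sel_b.size == 0:
        raise InvalidInputError("selections must be non-empty")
    if bin_width <= 0:
        raise InvalidInputError("bin_width must be positive")
    half_min_edge = min(float(f.box.min()) for f in frames) / 2.0
    if r_max > half_min_edge + 1e-12:
        raise InvalidInputError(
            f"r_max {r_max} nm exceeds half the smallest box edge "
            f"({half_min_edge:.4g} nm)"
        )
    n_bins = int(round(r_max / bin_width))
    edges = np.linspace(0.0, n_bins * bin_width, n_bins + 1)
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)

    g_acc = np.zeros(n_bins)
    n_common = np.intersect1d(sel_a, sel_b).size
    for f in frames:
        xa = f.coordinates[sel_a]
        xb = f.coordinates[sel_b]
        counts = np.zeros(n_bins)
        for start, r in _pair_distances_chunked(xa, xb, f.box):
            # drop self pairs: same global index shows up at distance 0
            sub_a = sel_a[start : start + r.shape[0]]
            self_mask = sub_a[:, None] == sel_b[None, :]
            r = np.where(self_mask, np.inf, r)
            counts += np.histogram(r, bins=edges)[0]
        n_pairs = sel_a.size * sel_b.size - n_common
        ideal = n_pairs / f.volume * shell_vol
        g_acc += counts / ideal
    g = g_acc / len(frames)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return RdfProfile(
        bin_centers=centers, g=g, bin_width=bin_width, n_frames=len(frames)
    )


def _rdf_from_points(
    points: np.ndarray,
    frames: list[Frame],
    selection_b: np.ndarray,
    bin_width: float,
    r_max: float,
) -> RdfProfile:
    """g(r) of selection_b around one reference point per frame."""
    n_bins = int(round(r_max / bin_width))
    edges = np.linspace(0.0, n_bins * bin_width, n_bins + 1)
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    g_acc = np.zeros(n_bins)
    for f, p in zip(frames, points):
        d = minimum_image(f.coordinates[selection_b] - p[None, :], f.box)
        r = np.linalg.norm(d, axis=1)
        counts = np.histogram(r, bins=edges)[0]
        ideal = selection_b.size / f.volume * shell_vol
        g_acc += counts / ideal
    centers = 0.5 * (edges[:-1] + edges[1:])
    return RdfProfile(
        bin_centers=centers, g=g_acc / len(frames), bin_width=bin_width,
        n_frames=len(frames),
    )


def kb_integral(
    rdf: RdfProfile,
    upper_boundary: float,
    molar_fractions: tuple[float, float] | None = None,
    starred: bool = False,
) -> KbResult:
    """Kirkwood–Buff integral G = ∫₀ᴿ 4πr²(g−1) dr on the binned profile.

    The integrand is trapezoided over bin centers with an r = 0 anchor where
    g = 0 (the excluded origin contributes −1 over its shell).  The starred
    variant multiplies by x_A·x_B, turning the excess volume into a
    contact-number-like quantity comparable across systems.
    """
    centers = rdf.bin_centers
    width = rdf.bin_width if rdf.bin_width > 0 else float(np.diff(centers).mean())
    r_edge = centers.max() + width / 2.0
    if upper_boundary <= 0 or upper_boundary > r_edge + 1e-12:
        raise InvalidInputError(
            f"upper boundary {upper_boundary} nm outside profile range "
            f"(last bin edge {r_edge:.4g} nm)"
        )
    # the profile is piecewise over bins; carry the last bin's g to its edge
    r = np.concatenate(([0.0], centers, [r_edge]))
    g = np.concatenate(([0.0], rdf.g, [rdf.g[-1]]))
    integrand = 4.0 * np.pi * r**2 * (g - 1.0)
    # integrate to the exact boundary, interpolating the last segment
    inside = r <= upper_boundary + 1e-12
    r_in = r[inside]
    y_in = integrand[inside]
    if r_in[-1] < upper_boundary - 1e-12:
        y_end = float(np.interp(upper_boundary, r, integrand))
        r_in = np.append(r_in, upper_boundary)
        y_in = np.append(y_in, y_end)
    G = float(np.trapezoid(y_in, r_in))
    if starred:
        if molar_fractions is None:
            raise InvalidInputError("starred KB integral needs (x_A, x_B)")
        G *= molar_fractions[0] * molar_fractions[1]
    return KbResult(G=G, upper_boundary=upper_boundary, starred=starred)


def heavy_atom_fractions(
    frame: Frame, species: Sequence[str]
) -> dict[str, float]:
    """Molar fractions by normalized heavy-atom counts over the given species."""
    counts = {}
    for sp in species:
        counts[sp] = select(frame, species=sp, heavy_only=True).size
    total = sum(counts.values())
    if total == 0:
        raise InvalidInputError("no heavy atoms in the requested species")
    return {sp: c / total for sp, c in counts.items()}


def delta_coefficient(
    x_b: float, g_ab: float, weighted_g_sum: float, corr_radius: float = 1.5
) -> float:
    """δ_B = x_B (G_AB − Σ x_α G_Aα) / (V_corr + Σ x_α G_Aα) with the
    correlation volume V_corr = (4/3)π R³."""
    v_corr = 4.0 / 3.0 * np.pi * corr_radius**3
    return x_b * (g_ab - weighted_g_sum) / (v_corr + weighted_g_sum)


def preferential_solvation(
    traj: Trajectory | Frame,
    sorbate_species: str = "sorbate",
    solvent_species: Sequence[str] = ("LHA", "water", "calcium"),
    corr_radius: float = 1.5,
    bin_width: float = 0.02,
) -> dict[str, float]:
    """Preferential-solvation coefficient δ_B of each species B around the
    sorbate.

    δ_B = x_B (G_AB − Σ_α x_α G_Aα) / (V_corr + Σ_α x_α G_Aα), where G_AB is
    the Kirkwood–Buff integral of species B around the sorbate up to
    ``corr_radius``, x are molar fractions from normalized heavy-atom counts
    over the solvating species, and V_corr is the correlation-sphere volume.
    The reference point is the sorbate's center of geometry per frame;
    positive δ_B means the sorbate is preferentially surrounded by B relative
    to the bulk composition.
    """
    frames = [traj] if isinstance(traj, Frame) else list(traj)
    if not frames:
        raise InvalidInputError("empty trajectory")
    f0 = frames[0]
    sorb = select(f0, species=sorbate_species)
    if sorb.size == 0:
        raise InvalidInputError(f"no particles of species {sorbate_species!r}")
    half_min_edge = min(float(f.box.min()) for f in frames) / 2.0
    if corr_radius > half_min_edge + 1e-12:
        raise InvalidInputError(
            f"correlation radius {corr_radius} nm exceeds half the smallest "
            f"box edge ({half_min_edge:.4g} nm)"
        )
    x = heavy_atom_fractions(f0, solvent_species)
    # unwrap the sorbate around its first atom before taking the centroid so
    # a molecule split across the boundary gets a sensible center
    centers = []
    for f in frames:
        xs = f.coordinates[sorb]
        rel = minimum_image(xs - xs[0], f.box)
        centers.append(xs[0] + rel.mean(axis=0))
    centers = np.asarray(centers)

    G: dict[str, float] = {}
    for sp in solvent_species:
        sel = select(f0, species=sp, heavy_only=True)
        if sel.size == 0:
            raise InvalidInputError(f"species {sp!r} absent from the frame")
        rdf = _rdf_from_points(centers, frames, sel, bin_width, corr_radius)
        G[sp] = kb_integral(rdf, corr_radius).G
    g_bar = sum(x[sp] * G[sp] for sp in solvent_species)
    return {
        sp: delta_coefficient(x[sp], G[sp], g_bar, corr_radius)
        for sp in solvent_species
    }


def hydrogen_bonds(
    frame: Frame,
    donors: Sequence[tuple[int, int]],
    acceptors: Sequence[int],
    criterion: HBondCriterion = HBondCriterion(),
) -> int:
    """Count geometric hydrogen bonds among (donor, hydrogen, acceptor)
    triples: H···A distance ≤ bound and D–H···A angle ≥ bound, both under the
    minimum-image convention and inclusive at the boundary."""
    if len(donors) == 0 or len(acceptors) == 0:
        return 0
    acc = np.asarray(acceptors, dtype=int)
    cos_max = math.cos(math.radians(criterion.min_donor_angle))
    count = 0
    for d_idx, h_idx in donors:
        xh = frame.coordinates[h_idx]
        xd = frame.coordinates[d_idx]
        mask = (acc != d_idx) & (acc != h_idx)
        if not mask.any():
            continue
        xa = frame.coordinates[acc[mask]]
        ha = minimum_image(xa - xh[None, :], frame.box)
        r_ha = np.linalg.norm(ha, axis=1)
        near = r_ha <= criterion.max_ha_distance + 1e-12
        if not near.any():
            continue
        hd = minimum_image(xd - xh, frame.box)
        r_hd = np.linalg.norm(hd)
        cosang = (ha[near] @ hd) / (r_ha[near] * r_hd)
        # D-H...A angle >= bound  <=>  cos(angle at H) <= cos(bound)
        count += int(np.sum(cosang <= cos_max + 1e-12))
    return count


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + math.sqrt(5.0)) * i
    return np.column_stack(
        (np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi))
    )


def sasa(
    frame: Frame,
    selection: np.ndarray | None = None,
    probe_radius: float = 0.14,
    n_sphere_points: int = 960,
) -> SasaResult:
    """Shrake–Rupley solvent-accessible surface area of a selection.

    Each heavy atom is inflated by the probe radius and sampled with a
    deterministic spiral point set; points buried inside any neighbour's
    inflated sphere are discarded.  Hydrogens are merged with their heavy
    atoms (united-atom convention) and never carry surface themselves.
    Per-atom areas are attributed to the carbon or heteroatom class.
    """
    if frame.radius is None:
        raise InvalidInputError("frame carries no SASA radii")
    if selection is None:
        selection = np.arange(frame.n_atoms)
    sel = np.asarray(selection, dtype=int)
    sel = sel[frame.element_class[sel] != "hydrogen"]
    if sel.size == 0:
        raise InvalidInputError("selection contains no heavy atoms")
    radii = frame.radius[sel]
    if np.any(radii <= 0):
        raise InvalidInputError("zero or negative SASA radius in selection")
    pts = _sphere_points(n_sphere_points)
    coords = frame.coordinates[sel]
    inflated = radii + probe_radius
    areas = np.zeros(sel.size)
    for i in range(sel.size):
        surface = coords[i] + inflated[i] * pts
        exposed = np.ones(n_sphere_points, dtype=bool)
        for j in range(sel.size):
            if j == i:
                continue
            dij = minimum_image(coords[j] - coords[i], frame.box)
            if np.linalg.norm(dij) >= inflated[i] + inflated[j]:
                continue
            d = minimum_image(surface - (coords[i] + dij)[None, :], frame.box)
            exposed &= np.einsum("ij,ij->i", d, d) > inflated[j] ** 2
            if not exposed.any():
                break
        areas[i] = 4.0 * np.pi * inflated[i] ** 2 * exposed.mean()
    total = float(areas.sum())
    carbon = float(areas[frame.element_class[sel] == "carbon"].sum())
    hetero = float(areas[frame.element_class[sel] == "heteroatom"].sum())
    if total > 0:
        cf, hf = carbon / total, hetero / total
    else:
        cf = hf = 0.0
    return SasaResult(total=total, carbon_fraction=cf, heteroatom_fraction=hf)


def pair_interaction_energy(
    frame: Frame,
    group_a: np.ndarray,
    group_b: np.ndarray,
    cutoff: float = DEFAULT_CUTOFF,
    eps_rf: float = DEFAULT_EPS_RF,
) -> tuple[float, float]:
    """Non-bonded interaction energy between two groups: (electrostatic, vdW).

    Sums over unique A–B pairs within the cutoff (minimum image).  The
    Lennard-Jones term uses geometric-mean combination of per-particle C6/C12;
    the Coulomb term includes the reaction-field correction for a homogeneous
    dielectric (permittivity ``eps_rf``) outside the cutoff sphere at zero
    ionic strength:

        E_el = f q_i q_j [ 1/r + C_rf r²/(2 R_c³) − (1 + C_rf/2)/R_c ]

    with C_rf = (2ε − 2)/(2ε + 1).
    """
    for attr in ("charge", "lj_c6", "lj_c12"):
        if getattr(frame, attr) is None:
            raise InvalidInputError(f"frame carries no {attr} parameters")
    a = np.asarray(group_a, dtype=int)
    b = np.asarray(group_b, dtype=int)
    if a.size == 0 or b.size == 0:
        raise InvalidInputError("groups must be non-empty")
    ii, jj = np.meshgrid(a, b, indexing="ij")
    ii, jj = ii.ravel(), jj.ravel()
    keep = ii != jj
    # count each unordered pair once even if the groups overlap
    both = np.isin(ii, b) & np.isin(jj, a)
    keep &= (~both) | (ii < jj)
    ii, jj = ii[keep], jj[keep]
    d = minimum_image(frame.coordinates[jj] - frame.coordinates[ii], frame.box)
    r = np.linalg.norm(d, axis=1)
    within = r <= cutoff
    ii, jj, r = ii[within], jj[within], r[within]
    if r.size == 0:
        return 0.0, 0.0
    c_rf = (2.0 * eps_rf - 2.0) / (2.0 * eps_rf + 1.0)
    qq = frame.charge[ii] * frame.charge[jj]
    elec = COULOMB_KJ_NM_PER_MOL_E2 * qq * (
        1.0 / r + c_rf * r**2 / (2.0 * cutoff**3) - (1.0 + c_rf / 2.0) / cutoff
    )
    c6 = np.sqrt(frame.lj_c6[ii] * frame.lj_c6[jj])
    c12 = np.sqrt(frame.lj_c12[ii] * frame.lj_c12[jj])
    inv6 = 1.0 / r**6
    vdw = c12 * inv6**2 - c6 * inv6
    return float(elec.sum()), float(vdw.sum())
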