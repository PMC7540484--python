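"""Synthetic inputs with the statistical structure the analysis assumes.

These generators stand in for the molecular-dynamics engine so the full
pipeline runs at desk scale: Gaussian forward/reverse work distributions
exactly satisfying the Crooks fluctuation relation, polynomial λ-curves with
known integrals, uniform and two-region clustered particle boxes, frames with
planted hydrogen-bond geometries, and the embedded 18-compound sorption
free-energy table.  Every generator takes an explicit seed and stores its
ground truth alongside the data.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import DEFAULT_TEMPERATURE, rt
from .errors import InvalidInputError
from .lambda_integration import LambdaCurve
from .structure_metrics import Frame
from .thermo_cycles import CompoundRecord
from .work_estimators import Direction, WorkSample, WorkSet

__all__ = [
    "crooks_gaussian_workset",
    "polynomial_lambda_curve",
    "ideal_gas_box",
    "clustered_mixture_box",
    "planted_hbond_frame",
    "table1_fixture",
    "ClusteredBox",
    "PlantedHBondFrame",
]

_CLASS_BY_SPECIES = {
    "sorbate": "carbon",
    "LHA": "carbon",
    "water": "heteroatom",
    "calcium": "heteroatom",
}


def crooks_gaussian_workset(
    dg_true: float,
    sigma: float,
    temperature: float = DEFAULT_TEMPERATURE,
    n_per_direction: int = 75,
    seed: int | tuple = 0,
    n_models: int = 3,
    student_t_df: float | None = None,
) -> WorkSet:
    """Bidirectional Gaussian work samples satisfying the Crooks relation.

    Forward (removing) works are drawn from N(ΔG + σ²/2RT, σ) and reverse
    (growing) works from N(−ΔG + σ²/2RT, σ), so the negated-reverse
    distribution sits at ΔG − σ²/2RT and the two Gaussians cross exactly at
    ΔG.  The dissipated work on either side is σ²/2RT.  Samples are tagged
    with ``n_models`` replicate labels round-robin, mirroring pooling of
    independent model replicas.

    ``student_t_df`` replaces the Gaussian noise with scaled Student-t noise
    of the same spread (a heavier-tailed stress test of the estimators).
    """
    if sigma <= 0:
        raise InvalidInputError("sigma must be positive")
    if n_per_direction < 2:
        raise InvalidInputError("need at least 2 samples per direction")
    rng = np.random.default_rng(seed)
    kt = rt(temperature)
    dissip = sigma**2 / (2.0 * kt)

    def _noise(n: int) -> np.ndarray:
        if student_t_df is None:
            return rng.normal(0.0, sigma, n)
        if student_t_df <= 2:
            raise InvalidInputError("student_t_df must exceed 2")
        scale = sigma / math.sqrt(student_t_df / (student_t_df - 2.0))
        return scale * rng.standard_t(student_t_df, n)

    fwd = dg_true + dissip + _noise(n_per_direction)
    rev = -dg_true + dissip + _noise(n_per_direction)
    samples = []
    for i, w in enumerate(fwd):
        samples.append(
            WorkSample(float(w), Direction.FORWARD, f"M{i % n_models + 1}", i)
        )
    for i, w in enumerate(rev):
        samples.append(
            WorkSample(float(w), Direction.REVERSE, f"M{i % n_models + 1}", i)
        )
    return WorkSet(samples, temperature=temperature, truth=dg_true)


def polynomial_lambda_curve(
    coefficients,
    noise_sd: float = 0.0,
    n_runs: int = 5,
    n_lambda: int = 21,
    seed: int | tuple = 0,
) -> LambdaCurve:
    """⟨∂H/∂λ⟩ curves: a polynomial in λ plus iid Gaussian run noise.

    ``coefficients`` are ascending powers (c0 + c1 λ + ...); the analytic
    integral Σ c_k/(k+1) is stored as the curve's truth.
    """
    if n_lambda < 2:
        raise InvalidInputError("need at least 2 λ points")
    if noise_sd < 0:
        raise InvalidInputError("noise_sd must be non-negative")
    coeff = np.asarray(coefficients, dtype=float)
    rng = np.random.default_rng(seed)
    lam = np.linspace(0.0, 1.0, n_lambda)
    clean = np.polynomial.polynomial.polyval(lam, coeff)
    values = clean[None, :] + rng.normal(0.0, noise_sd, size=(n_runs, n_lambda))
    truth = float(np.sum(coeff / (np.arange(coeff.size) + 1.0)))
    return LambdaCurve(lambdas=lam, values=values, truth=truth)


def _species_counts(n: int, species_mix: dict[str, float]) -> dict[str, int]:
    total_frac = sum(species_mix.values())
    if total_frac <= 0:
        raise InvalidInputError("species fractions must sum to a positive value")
    raw = {sp: n * f / total_frac for sp, f in species_mix.items()}
    counts = {sp: int(math.floor(v)) for sp, v in raw.items()}
    # hand out the remainder by largest fractional part; a declared sorbate
    # species always gets at least one particle
    rem = n - sum(counts.values())
    order = sorted(raw, key=lambda sp: raw[sp] - counts[sp], reverse=True)
    for sp in order[:rem]:
        counts[sp] += 1
    if "sorbate" in counts and counts["sorbate"] == 0:
        donor = max((sp for sp in counts if sp != "sorbate"), key=counts.get)
        counts[donor] -= 1
        counts["sorbate"] = 1
    return counts


def _frame_from_positions(
    pos: np.ndarray, box: np.ndarray, species: list[str]
) -> Frame:
    species_arr = np.array(species)
    classes = np.array([_CLASS_BY_SPECIES.get(sp, "carbon") for sp in species])
    return Frame(
        coordinates=pos, box=box, species=species_arr, element_class=classes
    )


def ideal_gas_box(
    n: int = 2000,
    box_edges=(3.2, 3.2, 3.2),
    species_mix: dict[str, float] | None = None,
    seed: int | tuple = 0,
) -> Frame:
    """Uniform, structureless particle box: the null model for RDF/KB/δ.

    Positions are iid uniform over the box; species are assigned by the
    stated fractions (default: one sorbate in a LHA/water/calcium mixture).
    By construction g(r) = 1, all Kirkwood–Buff integrals vanish and no
    species is preferred around any other, up to sampling noise.
    """
    if n < 2:
        raise InvalidInputError("need at least 2 particles")
    if species_mix is None:
        species_mix = {"sorbate": 0.002, "LHA": 0.55, "water": 0.40, "calcium": 0.05}
    rng = np.random.default_rng(seed)
    box = np.asarray(box_edges, dtype=float)
    pos = rng.uniform(0.0, 1.0, size=(n, 3)) * box
    counts = _species_counts(n, species_mix)
    species: list[str] = []
    for sp, c in counts.items():
        species.extend([sp] * c)
    perm = rng.permutation(n)
    species = [species[i] for i in perm]
    return _frame_from_positions(pos, box, species)


@dataclass
class ClusteredBox:
    """A two-region mixture frame plus the planted preferential-solvation
    truth (expected sign of δ per species)."""

    frame: Frame
    expected_delta_sign: dict[str, int]


def clustered_mixture_box(
    n_per_species: dict[str, int] | None = None,
    association_strength: float = 4.0,
    sorbate_placement: str = "water_patch",
    box_edges=(3.2, 3.2, 3.2),
    seed: int | tuple = 0,
    n_sorbate_atoms: int = 5,
) -> ClusteredBox:
    """Two-region (water-rich / LHA-rich) mixture with a planted sorbate.

    The box is split along z into a water-rich lower half and an LHA-rich
    upper half; each water (LHA) particle falls in its own region with
    probability (1+s)/(2+s), where s = ``association_strength``, so s = 0
    degenerates to the uniform box and s → ∞ gives full demixing.  The
    sorbate is planted as a small atom cluster at the centre of the patch
    named by ``sorbate_placement`` and must therefore be preferentially
    surrounded by that patch's majority species.
    """
    if association_strength < 0:
        raise InvalidInputError("association_strength must be non-negative")
    if sorbate_placement not in ("water_patch", "LHA_patch"):
        raise InvalidInputError(
            "sorbate_placement must be 'water_patch' or 'LHA_patch'"
        )
    if n_per_species is None:
        n_per_species = {"LHA": 1000, "water": 800, "calcium": 60}
    rng = np.random.default_rng(seed)
    box = np.asarray(box_edges, dtype=float)
    lz = box[2]
    p_own = (1.0 + association_strength) / (2.0 + association_strength)
    own_region = {"water": (0.0, lz / 2.0), "LHA": (lz / 2.0, lz)}

    positions: list[np.ndarray] = []
    species: list[str] = []
    for sp, count in n_per_species.items():
        xy = rng.uniform(0.0, 1.0, size=(count, 2)) * box[:2]
        if sp in own_region:
            lo, hi = own_region[sp]
            other = (lz / 2.0, lz) if lo == 0.0 else (0.0, lz / 2.0)
            in_own = rng.random(count) < p_own
            z = np.where(
                in_own,
                rng.uniform(lo, hi, count),
                rng.uniform(other[0], other[1], count),
            )
        else:
            z = rng.uniform(0.0, lz, count)
        positions.append(np.column_stack((xy, z)))
        species.extend([sp] * count)

    patch_z = lz * (0.25 if sorbate_placement == "water_patch" else 0.75)
    centre = np.array([box[0] / 2.0, box[1] / 2.0, patch_z])
    sorb = centre[None, :] + rng.normal(0.0, 0.05, size=(n_sorbate_atoms, 3))
    positions.append(sorb)
    species.extend(["sorbate"] * n_sorbate_atoms)

    frame = _frame_from_positions(np.vstack(positions), box, species)
    if sorbate_placement == "water_patch":
        signs = {"water": +1, "LHA": -1}
    else:
        signs = {"water": -1, "LHA": +1}
    return ClusteredBox(frame=frame, expected_delta_sign=signs)


@dataclass
class PlantedHBondFrame:
    """A frame with known hydrogen-bond content: ``k_bonds`` ideal D–H···A
    triples plus decoys violating exactly one criterion each."""

    frame: Frame
    donors: list[tuple[int, int]]
    acceptors: list[int]
    k_bonds: int


def planted_hbond_frame(
    k_bonds: int,
    m_distance_decoys: int = 0,
    m_angle_decoys: int = 0,
    seed: int | tuple = 0,
) -> PlantedHBondFrame:
    """Plant D–H···A triples on a sparse grid.

    Ideal triples have H···A distance in [0.18, 0.24] nm and D–H···A angle
    in [150°, 180°]; distance decoys keep the good angle but sit at
    0.26–0.35 nm, angle decoys keep the good distance but bend to 90–130°.
    Grid spacing (1.2 nm) guarantees no accidental cross-triple bonds.
    """
    if min(k_bonds, m_distance_decoys, m_angle_decoys) < 0:
        raise InvalidInputError("counts must be non-negative")
    rng = np.random.default_rng(seed)
    total = k_bonds + m_distance_decoys + m_angle_decoys
    spacing = 1.2
    n_grid = max(2, math.ceil(total ** (1.0 / 3.0)))
    edge = n_grid * spacing
    box = np.array([edge, edge, edge])

    sites = []
    for i in range(n_grid):
        for j in range(n_grid):
            for k in range(n_grid):
                sites.append(spacing * (np.array([i, j, k]) + 0.5))
                if len(sites) == total:
                    break
            if len(sites) == total:
                break
        if len(sites) == total:
            break

    kinds = ["bond"] * k_bonds + ["dist"] * m_distance_decoys + ["angle"] * m_angle_decoys
    coords: list[np.ndarray] = []
    classes: list[str] = []
    donors: list[tuple[int, int]] = []
    acceptors: list[int] = []
    for site, kind in zip(sites, kinds):
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        d_pos = site
        h_pos = d_pos + 0.10 * u  # donor-hydrogen bond length 0.1 nm
        if kind == "dist":
            r_ha = rng.uniform(0.26, 0.35)
            theta = math.radians(rng.uniform(150.0, 180.0))
        elif kind == "angle":
            r_ha = rng.uniform(0.18, 0.24)
            theta = math.radians(rng.uniform(90.0, 130.0))
        else:
            r_ha = rng.uniform(0.18, 0.24)
            theta = math.radians(rng.uniform(150.0, 180.0))
        u_hd = (d_pos - h_pos) / 0.10
        w = rng.normal(size=3)
        w -= (w @ u_hd) * u_hd
        w /= np.linalg.norm(w)
        v = math.cos(theta) * u_hd + math.sin(theta) * w
        a_pos = h_pos + r_ha * v
        base = len(coords)
        coords.extend([d_pos, h_pos, a_pos])
        classes.extend(["heteroatom", "hydrogen", "heteroatom"])
        donors.append((base, base + 1))
        acceptors.append(base + 2)

    n = len(coords)
    frame = Frame(
        coordinates=np.array(coords).reshape(n, 3) % box,
        box=box,
        species=np.array(["LHA"] * n),
        element_class=np.array(classes),
    )
    return PlantedHBondFrame(
        frame=frame, donors=donors, acceptors=acceptors, k_bonds=k_bonds
    )


def table1_dataframe() -> pd.DataFrame:
    """The embedded 18-compound sorption free-energy table as a DataFrame."""
    ref = importlib.resources.files("somsorb").joinpath("data/table1.tsv")
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", comment="#")


def table1_fixture() -> list[CompoundRecord]:
    """The embedded 18-compound table as typed records."""
    df = table1_dataframe()
    return [
        CompoundRecord(
            name=row.name,
            group=row.group,
            dg_dry_calc=row.dg_dry_calc,
            dg_dry_err=row.dg_dry_err,
            dg_hyd_calc=row.dg_hyd_calc,
            dg_hyd_err=row.dg_hyd_err,
            ddg_calc=row.ddg_calc,
            ddg_err=row.ddg_err,
            ddg_exp_dry=row.ddg_exp_dry,
            ddg_exp_hyd=row.ddg_exp_hyd,
        )
        for row in df.itertuples(index=False)
    ]
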