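"""File formats, configuration, and the end-to-end pipeline driver.

Coordinates travel as GRO (fixed-column, nm) or XYZ files read and written
through MDAnalysis; per-particle annotations (species, element class, charge,
LJ parameters, SASA radius) live in a sidecar TSV keyed by atom index.  Work
values, λ-curves and property tables are headered TSV with ``#`` comments.
Every pipeline report embeds the seed and a hash of the configuration so
identical inputs yield identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .constants import (
    DEFAULT_CUTOFF,
    DEFAULT_EPS_RF,
    DEFAULT_TEMPERATURE,
)
from .errors import InvalidInputError, TableParseError
from .lambda_integration import LambdaCurve, ti_free_energy
from .property_ledger import correlation_table
from .structure_metrics import Frame, HBondCriterion, hydrogen_bonds, preferential_solvation
from .thermo_cycles import sorption_free_energy
from .work_estimators import Direction, WorkSample, WorkSet, bootstrap_estimate

__all__ = [
    "read_gro",
    "write_gro",
    "read_xyz",
    "read_annotations",
    "write_annotations",
    "read_work_table",
    "write_work_table",
    "read_lambda_table",
    "write_lambda_table",
    "read_property_table",
    "PipelineConfig",
    "run_pipeline",
]


def _mda():
    # MDAnalysis import is deferred: it is slow and only coordinate I/O needs it
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        import MDAnalysis as mda
    return mda


def read_gro(path: str | Path, annotations: str | Path | None = None) -> Frame:
    """Read a GRO file (positions in nm, trailing rectangular box line).

    An optional sidecar TSV supplies the per-particle annotations the bare
    format cannot carry; without it every particle is a carbon-class LHA
    site.
    """
    path = Path(path)
    mda = _mda()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path))
        coords = u.atoms.positions / 10.0  # Å -> nm
        dims = u.dimensions
    except Exception as exc:  # MDAnalysis raises assorted parse errors
        raise TableParseError(f"cannot parse GRO file {path}: {exc}") from exc
    if dims is None or np.all(dims[:3] == 0):
        raise TableParseError(f"{path}: missing or zero box line")
    box = np.asarray(dims[:3], dtype=float) / 10.0
    n = coords.shape[0]
    names = np.array([a.name for a in u.atoms])
    frame = Frame(
        coordinates=coords,
        box=box,
        species=np.array(["LHA"] * n),
        element_class=np.array(["carbon"] * n),
        names=names,
    )
    if annotations is not None:
        frame = read_annotations(annotations, frame)
    return frame


def write_gro(frame: Frame, path: str | Path, annotations: str | Path | None = None) -> None:
    """Write a frame as GRO (3-decimal nm positions; lossy quantization)."""
    path = Path(path)
    mda = _mda()
    n = frame.n_atoms
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(n, trajectory=True)
        names = frame.names if frame.names is not None else np.array(
            [f"P{i + 1}" for i in range(n)]
        )
        u.add_TopologyAttr("names", names)
        u.add_TopologyAttr("resnames", ["SYS"])
        u.atoms.positions = frame.coordinates * 10.0  # nm -> Å
        u.dimensions = [*(frame.box * 10.0), 90.0, 90.0, 90.0]
        u.atoms.write(str(path))
    if annotations is not None:
        write_annotations(frame, annotations)


def read_xyz(path: str | Path, box, annotations: str | Path | None = None) -> Frame:
    """Read an XYZ file (coordinates interpreted as nm; box supplied by the
    caller or the sidecar, since XYZ carries none)."""
    path = Path(path)
    mda = _mda()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path))
        coords = u.atoms.positions / 10.0
        names = np.array([a.name for a in u.atoms])
    except Exception as exc:
        raise TableParseError(f"cannot parse XYZ file {path}: {exc}") from exc
    n = coords.shape[0]
    frame = Frame(
        coordinates=coords,
        box=np.asarray(box, dtype=float),
        species=np.array(["LHA"] * n),
        element_class=np.array(["carbon"] * n),
        names=names,
    )
    if annotations is not None:
        frame = read_annotations(annotations, frame)
    return frame


_ANNOTATION_COLS = ("species", "element_class", "charge", "c6", "c12", "radius")


def read_annotations(path: str | Path, frame: Frame) -> Frame:
    """Attach a per-particle annotation sidecar TSV to a frame."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = {"index", "species", "element_class"} - set(df.columns)
    if missing:
        raise TableParseError(f"annotation table lacks columns {sorted(missing)}")
    if len(df) != frame.n_atoms:
        raise TableParseError(
            f"annotation rows ({len(df)}) do not match particle count "
            f"({frame.n_atoms})"
        )
    df = df.sort_values("index").reset_index(drop=True)
    if not np.array_equal(df["index"].to_numpy(), np.arange(frame.n_atoms)):
        raise TableParseError("annotation 'index' must cover 0..N-1 exactly once")
    kwargs = dict(
        coordinates=frame.coordinates,
        box=frame.box,
        species=df["species"].to_numpy(),
        element_class=df["element_class"].to_numpy(),
        names=frame.names,
    )
    for col, attr in (("charge", "charge"), ("c6", "lj_c6"),
                      ("c12", "lj_c12"), ("radius", "radius")):
        if col in df.columns:
            kwargs[attr] = df[col].to_numpy(dtype=float)
    return Frame(**kwargs)


def write_annotations(frame: Frame, path: str | Path) -> None:
    data = {
        "index": np.arange(frame.n_atoms),
        "species": frame.species,
        "element_class": frame.element_class,
    }
    for col, attr in (("charge", "charge"), ("c6", "lj_c6"),
                      ("c12", "lj_c12"), ("radius", "radius")):
        v = getattr(frame, attr)
        if v is not None:
            data[col] = v
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def read_work_table(
    path: str | Path,
    temperature: float = DEFAULT_TEMPERATURE,
    compound: str | None = None,
) -> WorkSet:
    """Read a non-equilibrium work table TSV into a WorkSet.

    Columns: compound, direction (forward|reverse), model_id, run_id,
    work_kJ_per_mol.  ``compound`` filters multi-compound tables.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"compound", "direction", "model_id", "run_id", "work_kJ_per_mol"}
    missing = required - set(df.columns)
    if missing:
        raise TableParseError(f"work table lacks columns {sorted(missing)}")
    if compound is not None:
        df = df[df["compound"] == compound]
    if df.empty:
        raise TableParseError("work table has no matching rows")
    bad = set(df["direction"].unique()) - {"forward", "reverse"}
    if bad:
        raise TableParseError(f"unknown direction labels: {sorted(bad)}")
    works = pd.to_numeric(df["work_kJ_per_mol"], errors="coerce")
    if works.isna().any():
        row = int(works.index[works.isna()][0])
        raise TableParseError(f"non-numeric work value at row {row}")
    samples = [
        WorkSample(float(w), Direction(d), str(m), int(r))
        for w, d, m, r in zip(works, df["direction"], df["model_id"], df["run_id"])
    ]
    return WorkSet(samples, temperature=temperature)


def write_work_table(ws: WorkSet, path: str | Path, compound: str = "compound") -> None:
    rows = [
        dict(compound=compound, direction=s.direction.value, model_id=s.model_id,
             run_id=s.run_id, work_kJ_per_mol=s.work)
        for s in ws.samples
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_lambda_table(path: str | Path) -> LambdaCurve:
    """Read a λ-curve TSV (columns run_id, lambda, dHdl_kJ_per_mol)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"run_id", "lambda", "dHdl_kJ_per_mol"}
    missing = required - set(df.columns)
    if missing:
        raise TableParseError(f"λ table lacks columns {sorted(missing)}")
    if df.duplicated(subset=["run_id", "lambda"]).any():
        raise TableParseError("duplicate (run_id, lambda) rows")
    pivot = df.pivot(index="run_id", columns="lambda", values="dHdl_kJ_per_mol")
    if pivot.isna().any().any():
        raise TableParseError("every run must cover every λ point")
    try:
        return LambdaCurve(
            lambdas=pivot.columns.to_numpy(dtype=float),
            values=pivot.to_numpy(dtype=float),
        )
    except InvalidInputError as exc:
        raise TableParseError(str(exc)) from exc


def write_lambda_table(curve: LambdaCurve, path: str | Path) -> None:
    rows = []
    for run, row in enumerate(curve.values):
        for lam, v in zip(curve.lambdas, row):
            rows.append(dict(run_id=run, **{"lambda": lam}, dHdl_kJ_per_mol=v))
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_property_table(path: str | Path, response: str = "dG_sorb") -> pd.DataFrame:
    """Read a compound-by-property TSV; validates the response column."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if response not in df.columns:
        raise TableParseError(f"property table lacks response column {response!r}")
    if df[response].isna().any():
        raise TableParseError("missing response values")
    if len(df) < 3:
        raise TableParseError("property table needs at least 3 compounds")
    return df


@dataclass
class PipelineConfig:
    """Declarative configuration of the end-to-end synthetic pipeline."""

    temperature: float = DEFAULT_TEMPERATURE
    n_boot: int = 1000
    seed: int = 0
    rdf_r_max: float = 1.5
    kb_boundaries: tuple[float, ...] = (0.3, 0.4, 0.5, 1.5)
    hbond: HBondCriterion = field(default_factory=HBondCriterion)
    sasa_probe: float = 0.14
    sasa_points: int = 960
    pair_cutoff: float = DEFAULT_CUTOFF
    eps_rf: float = DEFAULT_EPS_RF
    n_compounds: int = 6
    n_work_per_direction: int = 75
    work_sigma: float = 4.0
    n_frames_structure: int = 10

    def __post_init__(self) -> None:
        positive = dict(
            temperature=self.temperature, n_boot=self.n_boot,
            rdf_r_max=self.rdf_r_max, sasa_probe=self.sasa_probe,
            sasa_points=self.sasa_points, pair_cutoff=self.pair_cutoff,
            eps_rf=self.eps_rf,
        )
        for name, v in positive.items():
            if v <= 0:
                raise InvalidInputError(f"{name} must be positive, got {v}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "hbond" in raw:
            raw["hbond"] = HBondCriterion(**raw["hbond"])
        if "kb_boundaries" in raw:
            raw["kb_boundaries"] = tuple(raw["kb_boundaries"])
        return cls(**raw)

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full synthetic study end to end and return the JSON report.

    Stages: (1) generate Crooks-consistent work sets for ``n_compounds``
    planted sorption free energies in vacuum and matrix, estimate each by
    bootstrapped CGI and compose the thermodynamic cycle; (2) generate a
    clustered box and measure preferential solvation; (3) count planted
    hydrogen bonds; (4) correlate a planted per-compound property ledger
    with the recovered sorption free energies.  Deterministic given the seed.
    """
    from .synthetic_data import (
        clustered_mixture_box,
        crooks_gaussian_workset,
        planted_hbond_frame,
    )

    rng = np.random.default_rng(config.seed)
    report: dict = {
        "seed": config.seed,
        "config_hash": config.digest(),
        "version": __version__,
    }

    def _stage(name):
        def deco(fn):
            try:
                return fn()
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return deco

    # -- stage 1: free energies through the thermodynamic cycle -----------
    @_stage("free_energies")
    def free_energies():
        out = {}
        planted = {}
        hbond_capacity = {}
        for i in range(config.n_compounds):
            # planted H-bond capacity 0..3: each bond makes decoupling from
            # the matrix costlier, hence sorption more favourable
            cap = int(rng.integers(0, 4))
            dg_env = float(20.0 + 6.0 * cap + rng.normal(0.0, 1.0))
            dg_vac = float(-2.0 + rng.normal(0.0, 0.5))
            name = f"compound_{i + 1}"
            hbond_capacity[name] = cap
            planted[name] = dg_vac - dg_env
            est = {}
            for env, dg in (("vac", dg_vac), ("env", dg_env)):
                ws = crooks_gaussian_workset(
                    dg, config.work_sigma, config.temperature,
                    config.n_work_per_direction,
                    seed=(config.seed, i, 0 if env == "vac" else 1),
                )
                est[env] = bootstrap_estimate(
                    ws, "cgi", n_boot=config.n_boot, seed=(config.seed, i, 7)
                )
            sorb = sorption_free_energy(est["vac"], est["env"])
            out[name] = {
                "dG_vac": est["vac"].value, "dG_env": est["env"].value,
                "dG_sorb": sorb.value, "uncertainty": sorb.uncertainty,
                "planted": planted[name],
                "hbond_capacity": cap,
            }
        return out

    report["free_energies"] = free_energies

    # -- stage 2: preferential solvation on a clustered box ----------------
    @_stage("preferential_solvation")
    def prefsolv():
        deltas = {"water": [], "LHA": []}
        cb = None
        for j in range(config.n_frames_structure):
            cb = clustered_mixture_box(seed=(config.seed, 100 + j))
            d = preferential_solvation(cb.frame)
            for sp in deltas:
                deltas[sp].append(d[sp])
        return {
            "delta": {sp: float(np.mean(v)) for sp, v in deltas.items()},
            "expected_sign": cb.expected_delta_sign,
        }

    report["preferential_solvation"] = prefsolv

    # -- stage 3: hydrogen bonds -------------------------------------------
    @_stage("hydrogen_bonds")
    def hbonds():
        planted = planted_hbond_frame(8, 4, 4, seed=(config.seed, 200))
        n = hydrogen_bonds(
            planted.frame, planted.donors, planted.acceptors, config.hbond
        )
        return {"count": n, "planted": planted.k_bonds}

    report["hydrogen_bonds"] = hbonds

    # -- stage 4: property ledger ------------------------------------------
    @_stage("correlation_ledger")
    def ledger():
        fe = report["free_energies"]
        df = pd.DataFrame(
            {
                "dG_sorb": [fe[c]["dG_sorb"] for c in fe],
                "hbond_capacity": [float(fe[c]["hbond_capacity"]) for c in fe],
            },
            index=list(fe),
        )
        rep = correlation_table(df, response="dG_sorb")
        return {
            prop: {k: (v if isinstance(v, str) else float(v))
                   for k, v in row.items()}
            for prop, row in rep.table.iterrows()
        }

    report["correlation_ledger"] = ledger
    return report


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
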