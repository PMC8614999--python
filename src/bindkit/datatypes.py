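"""Domain containers shared across the package.

Parameter bundles validate their invariants eagerly in ``__post_init__`` so
that generators and fitters can assume well-formed inputs.  Coordinate data
is stored as plain float64 numpy arrays in angstrom; concentrations are molar,
volumes litres, temperatures kelvin, energies kcal/mol unless a field name
says otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .constants import TRP_LIFETIME_S

__all__ = [
    "QuenchParams",
    "ITCGeometry",
    "ITCParams",
    "DSCTransition",
    "PlantedPoseSpec",
    "HingeSpec",
    "TitrationSeries",
    "ITCExperiment",
    "Thermogram",
    "DoseResponse",
    "SternVolmerFit",
    "QuenchBindingFit",
    "ITCFit",
    "DSCFit",
    "IC50Fit",
    "Topology",
    "Structure",
    "Trajectory",
    "PoseEnsemble",
    "PlantedTruth",
    "Embedding",
    "SelectionResult",
    "DomainMap",
    "SeriesResult",
]


# ---------------------------------------------------------------------------
# generator parameter bundles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QuenchParams:
    """Ground truth for a static-quenching fluorescence titration.

    ``K_sv`` (M^-1) controls the Stern-Volmer slope while ``K_d`` (M) and
    ``n_sites`` describe the underlying binding equilibrium; in the static
    model the two may be set independently.
    """

    K_sv: float
    F0: float = 1.0e6
    n_sites: float = 1.0
    K_d: float = 1.0e-5
    tau: float = TRP_LIFETIME_S

    def __post_init__(self) -> None:
        if self.K_sv < 0:
            raise ValueError("K_sv must be >= 0")
        for name in ("F0", "n_sites", "K_d", "tau"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class ITCGeometry:
    """Titration-calorimeter cell/syringe geometry.

    Defaults reproduce a displacement-cell experiment with a 0.2 mL cell,
    25 µM macromolecule, 250 µM ligand in the syringe and a schedule of one
    0.4 µL priming shot followed by nineteen 2 µL injections.
    """

    cell_volume: float = 0.2e-3
    cell_conc: float = 25e-6
    syringe_conc: float = 250e-6
    injection_volumes: tuple = (0.4e-6,) + (2.0e-6,) * 19
    temperature: float = 298.15

    def __post_init__(self) -> None:
        if self.cell_volume <= 0 or self.cell_conc <= 0 or self.syringe_conc <= 0:
            raise ValueError("volumes and concentrations must be positive")
        vols = tuple(float(v) for v in self.injection_volumes)
        if len(vols) == 0:
            raise ValueError("injection schedule must be non-empty")
        if any(v <= 0 for v in vols):
            raise ValueError("injection volumes must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (kelvin)")
        object.__setattr__(self, "injection_volumes", vols)

    @property
    def n_injections(self) -> int:
        return len(self.injection_volumes)


@dataclass(frozen=True)
class ITCParams:
    """One-set-of-sites binding parameters: stoichiometry n, K_d (M), dH (kcal/mol)."""

    n: float
    K_d: float
    dH: float

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        if self.K_d <= 0:
            raise ValueError("K_d must be positive")

    @property
    def Ka(self) -> float:
        return 1.0 / self.K_d


@dataclass(frozen=True)
class DSCTransition:
    """One two-state thermal transition: T_m (K), calorimetric and van't Hoff enthalpies (kcal/mol).

    dH_cal != dH_vH marks a non-two-state transition when several such peaks
    are summed.
    """

    T_m: float
    dH_cal: float
    dH_vH: float

    def __post_init__(self) -> None:
        if self.T_m <= 0:
            raise ValueError("T_m must be positive (kelvin)")
        if self.dH_cal <= 0 or self.dH_vH <= 0:
            raise ValueError("enthalpies must be positive")


@dataclass(frozen=True)
class PlantedPoseSpec:
    """Blueprint for a pose ensemble with known spatial clusters.

    ``centers`` is an (n_clusters, 3) array of cluster centres in angstrom,
    ``spread`` the per-cluster isotropic s.d., ``counts`` poses per cluster.
    ``ligand_template`` is a list of (element, xyz) pairs shared by every
    pose; ``score_model`` holds per-cluster (mean, sd) of the docking score
    (lower = better).
    """

    centers: np.ndarray
    spread: Sequence[float]
    counts: Sequence[int]
    ligand_template: Sequence[tuple]
    score_model: Sequence[tuple]

    def __post_init__(self) -> None:
        centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        if centers.shape[1] != 3:
            raise ValueError("centers must be (n_clusters, 3)")
        object.__setattr__(self, "centers", centers)
        k = centers.shape[0]
        if not (len(self.spread) == len(self.counts) == len(self.score_model) == k):
            raise ValueError("spread, counts and score_model must match n_clusters")
        if any(int(c) < 1 for c in self.counts):
            raise ValueError("each cluster needs at least one pose")
        if len(self.ligand_template) == 0:
            raise ValueError("ligand template must contain atoms")

    @property
    def n_clusters(self) -> int:
        return self.centers.shape[0]


@dataclass(frozen=True)
class HingeSpec:
    """Two rigid pseudo-domains whose closest approach closes linearly in time.

    The probe atom sits on the fixed domain's facing surface and becomes
    buried between the domains as the gap shrinks from ``start_gap`` to
    ``end_gap`` (angstrom).
    """

    n_frames: int = 100
    domain_sizes: tuple = (27, 27)
    start_gap: float = 15.0
    end_gap: float = 4.0
    probe_index: int | None = None
    jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")
        if self.start_gap <= 0 or self.end_gap <= 0:
            raise ValueError("gaps must be positive")
        if self.end_gap >= self.start_gap:
            raise ValueError("closing trajectory requires end_gap < start_gap")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")


# ---------------------------------------------------------------------------
# measurement series
# ---------------------------------------------------------------------------

@dataclass
class TitrationSeries:
    """Fluorescence-quenching titration: ligand concentration (M) vs intensity."""

    ligand_conc: np.ndarray
    fluorescence: np.ndarray
    protein_conc: float = 0.1e-6
    temperature: float = 298.15
    reduced_flag: bool = True
    truth: dict | None = None

    def __post_init__(self) -> None:
        self.ligand_conc = np.asarray(self.ligand_conc, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.ligand_conc.shape != self.fluorescence.shape:
            raise ValueError("ligand_conc and fluorescence must have equal length")
        if self.ligand_conc.size and self.ligand_conc[0] != 0.0:
            raise ValueError("first concentration must be 0 (the F0 point)")
        if np.any(self.fluorescence <= 0):
            raise ValueError("fluorescence must be positive")


@dataclass
class ITCExperiment:
    """Integrated per-injection heats (µcal) plus the cell/syringe geometry."""

    geometry: ITCGeometry
    heats: np.ndarray
    dilution_heats: np.ndarray | None = None
    truth: dict | None = None

    def __post_init__(self) -> None:
        self.heats = np.asarray(self.heats, dtype=float)
        if self.heats.shape != (self.geometry.n_injections,):
            raise ValueError("heats length must equal the injection count")
        if self.dilution_heats is not None:
            self.dilution_heats = np.asarray(self.dilution_heats, dtype=float)
            if self.dilution_heats.shape != self.heats.shape:
                raise ValueError("dilution blank must match heats length")


@dataclass
class Thermogram:
    """DSC trace: temperature grid (K) vs excess heat capacity (kcal mol^-1 K^-1)."""

    temperature: np.ndarray
    excess_cp: np.ndarray
    truth: dict | None = None

    def __post_init__(self) -> None:
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.excess_cp = np.asarray(self.excess_cp, dtype=float)
        if self.temperature.shape != self.excess_cp.shape:
            raise ValueError("temperature and excess_cp must have equal length")
        if np.any(np.diff(self.temperature) <= 0):
            raise ValueError("temperature grid must be strictly increasing")


@dataclass
class DoseResponse:
    """Inhibitor dose-response: concentration (M) vs residual activity."""

    conc: np.ndarray
    activity: np.ndarray
    truth: dict | None = None

    def __post_init__(self) -> None:
        self.conc = np.asarray(self.conc, dtype=float)
        self.activity = np.asarray(self.activity, dtype=float)
        if self.conc.shape != self.activity.shape:
            raise ValueError("conc and activity must have equal length")
        if np.any(self.conc <= 0):
            raise ValueError("concentrations must be positive")


# ---------------------------------------------------------------------------
# fit results
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SternVolmerFit:
    K_sv: float
    K_sv_se: float
    K_q: float
    intercept: float
    r_squared: float
    monotone_warning: bool = False


@dataclass(frozen=True)
class QuenchBindingFit:
    K_d: float
    n_sites: float
    iterations: int
    converged: bool


@dataclass(frozen=True)
class ITCFit:
    n: float
    K_d: float
    dH: float
    dG: float
    TdS: float
    dilution_offset: float
    residual_norm: float
    c_value: float
    K_d_ci95: tuple = (float("nan"), float("nan"))


@dataclass(frozen=True)
class DSCFit:
    transitions: tuple
    baseline: tuple
    residual_norm: float


@dataclass(frozen=True)
class IC50Fit:
    ic50: float
    hill: float
    top: float
    bottom: float
    ci95: tuple
    n_boot: int


# ---------------------------------------------------------------------------
# structural containers
# ---------------------------------------------------------------------------

@dataclass
class Topology:
    """Ordered atom records over which all frames/poses are defined."""

    element: np.ndarray
    atom_name: np.ndarray
    res_id: np.ndarray
    res_name: np.ndarray
    chain: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.element)
        for f in ("atom_name", "res_id", "res_name", "chain"):
            if len(getattr(self, f)) != n:
                raise ValueError("topology columns must have equal length")

    @property
    def n_atoms(self) -> int:
        return len(self.element)

    def heavy_mask(self) -> np.ndarray:
        return np.char.upper(self.element.astype("U4")) != "H"


@dataclass
class Structure:
    """A single conformation: topology plus one (N, 3) coordinate set."""

    topology: Topology
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (self.topology.n_atoms, 3):
            raise ValueError("coords must be (n_atoms, 3)")


@dataclass
class Trajectory:
    """Ordered coordinate frames over a fixed topology."""

    topology: Topology
    frames: np.ndarray
    frame_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1:] != (self.topology.n_atoms, 3):
            raise ValueError("frames must be (n_frames, n_atoms, 3)")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frame coordinates must be finite")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def frame(self, i: int) -> Structure:
        return Structure(self.topology, self.frames[i])


@dataclass
class PoseEnsemble:
    """Rigid ligand poses sharing one atom order, with scores and provenance.

    ``coords`` is (n_poses, n_atoms, 3); ``scores`` are docking scores with
    lower = better; ``provenance`` has columns snapshot_id, conformer_id,
    epimer.
    """

    element: np.ndarray
    atom_name: np.ndarray
    coords: np.ndarray
    scores: np.ndarray
    provenance: pd.DataFrame

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must be (n_poses, n_atoms, 3)")
        if self.coords.shape[1] != len(self.element):
            raise ValueError("atom table and coords disagree on atom count")
        if self.scores.shape != (self.coords.shape[0],):
            raise ValueError("one score per pose required")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("pose coordinates must be finite")
        if len(self.provenance) != self.coords.shape[0]:
            raise ValueError("provenance rows must match pose count")

    @property
    def n_poses(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def heavy_mask(self) -> np.ndarray:
        return np.char.upper(self.element.astype("U4")) != "H"

    def subset(self, indices) -> "PoseEnsemble":
        idx = np.asarray(indices, dtype=int)
        return PoseEnsemble(
            element=self.element,
            atom_name=self.atom_name,
            coords=self.coords[idx],
            scores=self.scores[idx],
            provenance=self.provenance.iloc[idx].reset_index(drop=True),
        )


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth accompanying a generated pose ensemble."""

    cluster_of: np.ndarray
    centers: np.ndarray


@dataclass(frozen=True)
class Embedding:
    """2-D principal-component embedding of pose coordinates."""

    points: np.ndarray
    explained_variance: tuple
    mean_vector: np.ndarray
    components: np.ndarray


@dataclass(frozen=True)
class SelectionResult:
    score_indices: np.ndarray
    kde_indices: np.ndarray
    union_indices: np.ndarray
    mdcom: float
    overlap_fraction: float
    density_at_selected: np.ndarray


@dataclass(frozen=True)
class DomainMap:
    """Named atom selections: label -> (chain, (first_resid, last_resid)).

    Resolution against a topology returns atom indices; every label must
    resolve to at least one atom.
    """

    selections: dict

    def resolve(self, topology: Topology, label: str) -> np.ndarray:
        if label not in self.selections:
            raise KeyError(f"unknown domain label {label!r}")
        chain, (lo, hi) = self.selections[label]
        mask = (
            (topology.chain == chain)
            & (topology.res_id >= lo)
            & (topology.res_id <= hi)
        )
        idx = np.nonzero(mask)[0]
        if idx.size == 0:
            raise ValueError(f"domain {label!r} resolves to no atoms")
        return idx


@dataclass
class SeriesResult:
    """Per-frame metric values with a label and the selection that produced them."""

    values: np.ndarray
    metric: str
    selection: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("series values must be finite")
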