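"""Synthetic experiment generators.

Every input the pipeline consumes can be generated here from explicit true
parameters, a design (concentrations / time grids), an i.i.d. Gaussian
noise level and a seed: equilibrium titrations, chase and association
fluorescence traces, SPR sensorgram sets, ELISA panels, and toy two-chain
complexes with a movable two-helix-like motif.  Noise-free outputs lie
exactly on the corresponding closed-form model, which keeps parameter
recovery tests interpretable.

Random streams are per-generator kind and seed-derived, so adding a
generator does not shift the draws of the others; identical (spec, seed)
inputs give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any
import warnings

import numpy as np
import pandas as pd

from .elisa import ElisaPanel
from .kinetics import KineticTrace, TitrationDataset
from .models import (
    ExponentialParams,
    IsothermParams,
    LangmuirParams,
    eval_exponential,
    eval_isotherm,
    eval_langmuir_sensorgram,
    ode_oracle,
)
from .spr import Sensorgram
from .structure import ATOM_COLUMNS, StructureModel

__all__ = [
    "SyntheticSpec",
    "ToyComplex",
    "ExcessConditionError",
    "gen_titration",
    "gen_chase",
    "gen_association_series",
    "gen_sensorgram_set",
    "gen_elisa_panel",
    "gen_toy_complex",
    "default_titration_design",
    "generate",
]

# independent, stable sub-stream per generator kind
_STREAMS = {
    "titration": 1, "chase": 2, "association_series": 3,
    "sensorgram_set": 4, "elisa_panel": 5, "toy_complex": 6,
}


class ExcessConditionError(ValueError):
    """Pseudo-first-order excess condition violated beyond repair."""


def _rng(kind: str, seed: int) -> np.random.Generator:
    return np.random.default_rng([_STREAMS[kind], int(seed)])


@dataclass
class SyntheticSpec:
    """Declarative description of one synthetic experiment.

    ``true_params`` and ``design`` are kind-specific keyword dictionaries
    passed through to the matching ``gen_*`` function.
    """

    experiment_kind: str
    true_params: dict[str, Any]
    design: dict[str, Any] = field(default_factory=dict)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.experiment_kind not in _STREAMS:
            raise ValueError(f"unknown experiment kind {self.experiment_kind!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def generate(spec: SyntheticSpec):
    """Dispatch a :class:`SyntheticSpec` to the matching generator."""
    fn = {
        "titration": gen_titration,
        "chase": gen_chase,
        "association_series": gen_association_series,
        "sensorgram_set": gen_sensorgram_set,
        "elisa_panel": gen_elisa_panel,
        "toy_complex": gen_toy_complex,
    }[spec.experiment_kind]
    return fn(**spec.true_params, **spec.design, noise_sd=spec.noise_sd, seed=spec.seed) \
        if spec.experiment_kind != "toy_complex" \
        else fn(**spec.true_params, **spec.design, seed=spec.seed)


def default_titration_design(k_d: float, probe_conc: float, n_points: int = 12) -> np.ndarray:
    """Log-spaced ligand concentrations from D*/10 to max(20 K_D, 5 D*).

    Covers both the depletion-dominated regime (ligand below probe) and the
    saturation plateau.
    """
    lo = probe_conc / 10.0
    hi = max(20.0 * k_d, 5.0 * probe_conc)
    return np.geomspace(lo, hi, n_points)


def gen_titration(
    k_d: float,
    fluo_max: float,
    probe_conc: float,
    ligand_conc: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> TitrationDataset:
    """Synthetic equilibrium titration on the tight-binding isotherm."""
    params = IsothermParams(k_d, fluo_max, probe_conc)
    t = (
        np.asarray(ligand_conc, dtype=float)
        if ligand_conc is not None
        else default_titration_design(k_d, probe_conc)
    )
    signal = eval_isotherm(params, t)
    if noise_sd > 0:
        signal = signal + _rng("titration", seed).normal(0.0, noise_sd, t.shape)
    return TitrationDataset(
        ligand_conc=t,
        delta_fluo=signal,
        probe_conc=probe_conc,
        label=(
            f"synthetic titration seed={seed} k_d={k_d!r} "
            f"fluo_max={fluo_max!r} noise_sd={noise_sd!r}"
        ),
    )


def gen_chase(
    k_off: float,
    amplitude: float = 1.0,
    baseline: float = 0.0,
    t_max: float | None = None,
    n_points: int = 200,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> KineticTrace:
    """Chase (competition) dissociation trace: mono-exponential decay at
    ``k_obs = k_off`` (saturating unlabeled competitor)."""
    t_max = t_max if t_max is not None else 5.0 / k_off
    t = np.linspace(0.0, t_max, n_points)
    params = ExponentialParams(baseline, amplitude, k_off, "decay")
    signal = eval_exponential(params, t)
    if noise_sd > 0:
        signal = signal + _rng("chase", seed).normal(0.0, noise_sd, t.shape)
    return KineticTrace(
        time=t, signal=signal,
        label=f"synthetic chase seed={seed} k_off={k_off!r} noise_sd={noise_sd!r}",
    )


def gen_association_series(
    k_on: float,
    k_off: float,
    probe_conc: float,
    ligand_concs: np.ndarray,
    fluo_max: float = 1.0,
    n_points: int = 200,
    noise_sd: float = 0.0,
    seed: int = 0,
    exact_ode: bool = False,
) -> list[KineticTrace]:
    """Pseudo-first-order association traces over a concentration series.

    Each trace is an exponential rise with ``k_obs = k_on [T] + k_off``;
    the amplitude scales with the equilibrium bound fraction.  Ligand
    excess below 5x the probe concentration triggers a warning, below 2x an
    :class:`ExcessConditionError`.  With ``exact_ode=True`` the traces are
    integrated with the full second-order mass-action scheme instead of the
    closed form (used by property tests to quantify the pseudo-first-order
    approximation).
    """
    concs = np.asarray(ligand_concs, dtype=float)
    if np.any(concs < 2.0 * probe_conc):
        raise ExcessConditionError(
            "ligand excess below 2x the probe concentration: "
            "pseudo-first-order analysis invalid"
        )
    if np.any(concs < 5.0 * probe_conc):
        warnings.warn(
            "ligand excess below 5x the probe concentration; "
            "k_obs = k_on[T] + k_off is approximate",
            stacklevel=2,
        )
    rng = _rng("association_series", seed)
    traces = []
    k_d = k_off / k_on if k_on > 0 else np.inf
    for conc in concs:
        k_obs = k_on * conc + k_off
        t = np.linspace(0.0, 5.0 / k_obs, n_points)
        amplitude = fluo_max * conc / (conc + k_d) if np.isfinite(k_d) else fluo_max
        if exact_ode:
            traj = ode_oracle(k_on, k_off, probe_conc, conc, t)
            signal = fluo_max * traj.complex / probe_conc
        else:
            params = ExponentialParams(0.0, amplitude, k_obs, "rise")
            signal = eval_exponential(params, t)
        if noise_sd > 0:
            signal = signal + rng.normal(0.0, noise_sd, t.shape)
        traces.append(
            KineticTrace(
                time=t, signal=signal, ligand_conc=float(conc),
                label=(
                    f"synthetic association seed={seed} k_on={k_on!r} "
                    f"k_off={k_off!r} conc={conc!r} noise_sd={noise_sd!r}"
                ),
            )
        )
    return traces


def gen_sensorgram_set(
    k_on: float,
    k_off: float,
    r_max: float,
    concentrations: np.ndarray | None = None,
    n_concentrations: int = 5,
    t_assoc: float = 180.0,
    t_dissoc: float = 420.0,
    n_points_per_phase: int = 200,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[Sensorgram]:
    """Synthetic 1:1 Langmuir sensorgram set over a concentration series.

    Default design: ``n_concentrations`` analyte concentrations spanning
    K_D/4 to 4 K_D geometrically (injections centered on the expected K_D),
    a 180 s injection and a 420 s wash, plus a short pre-injection baseline
    segment.
    """
    k_d = k_off / k_on
    concs = (
        np.asarray(concentrations, dtype=float)
        if concentrations is not None
        else np.geomspace(k_d / 4.0, 4.0 * k_d, n_concentrations)
    )
    rng = _rng("sensorgram_set", seed)
    out = []
    t_pre = np.linspace(-10.0, -0.5, 20)
    t_a = np.linspace(0.0, t_assoc, n_points_per_phase)
    t_d = np.linspace(t_assoc, t_assoc + t_dissoc, n_points_per_phase)[1:]
    for conc in concs:
        params = LangmuirParams(k_on, k_off, r_max, float(conc))
        r_a, r_d = eval_langmuir_sensorgram(params, t_a, t_d)
        time = np.concatenate([t_pre, t_a, t_d])
        resp = np.concatenate([np.zeros_like(t_pre), r_a, r_d])
        if noise_sd > 0:
            resp = resp + rng.normal(0.0, noise_sd, resp.shape)
        out.append(
            Sensorgram(
                time=time, response=resp, analyte_conc=float(conc),
                assoc_window=(0.0, t_assoc),
                dissoc_window=(t_assoc, t_assoc + t_dissoc),
                label=(
                    f"synthetic sensorgram seed={seed} k_on={k_on!r} "
                    f"k_off={k_off!r} r_max={r_max!r} conc={conc!r}"
                ),
            )
        )
    return out


# ratio bands for the three affinity classes (variant/reference signal
# under competitor): low < 2x, medium 3-6x, high >= 8x
_CATEGORY_BANDS = {"low": (0.5, 2.0), "medium": (3.0, 6.0), "high": (8.0, 16.0)}


def gen_elisa_panel(
    true_categories: dict[str, str],
    reference: str = "parent",
    reference_signal: float = 0.2,
    replicates: int = 2,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ElisaPanel:
    """Synthetic ELISA panel with variants drawn inside known ratio bands.

    The reference (parent) binder is added automatically at ratio 1.  The
    buffer condition compresses the differentiation (square-root of the
    competitor ratio), mimicking the weaker contrast seen without a
    rebinding competitor.
    """
    rng = _rng("elisa_panel", seed)
    rows = []

    def add_variant(name: str, ratio: float) -> None:
        for condition, r in (("competitor", ratio), ("buffer", np.sqrt(ratio))):
            for rep in range(replicates):
                signal = reference_signal * r
                if noise_sd > 0:
                    signal += rng.normal(0.0, noise_sd)
                rows.append(
                    {
                        "variant": name, "condition": condition,
                        "replicate": rep, "signal": max(signal, 0.0),
                    }
                )

    add_variant(reference, 1.0)
    for name, category in true_categories.items():
        if category not in _CATEGORY_BANDS:
            raise ValueError(f"unknown category {category!r} for variant {name!r}")
        lo, hi = _CATEGORY_BANDS[category]
        add_variant(name, float(rng.uniform(lo, hi)))

    return ElisaPanel(
        data=pd.DataFrame(rows),
        reference=reference,
        true_categories=dict(true_categories),
        seed=seed,
    )


@dataclass
class ToyComplex:
    """A constructed two-chain complex with a movable cap-like motif.

    ``bound`` holds receptor chain R plus binder chain B with the motif
    rotated by ``rotation_deg`` about the recorded axis; ``apo_binder`` is
    the binder with the motif in the unrotated pose, in the same frame.
    In the unrotated pose exactly ``clash_count`` receptor/motif atom pairs
    lie within 2 A; the rotation relieves them (guaranteed for rotations
    of roughly 20 degrees and above at the default geometry).
    ``interface_pairs`` are rotation-independent receptor/binder contacts
    placed at ``interface_distance``.
    """

    bound: StructureModel
    apo_binder: StructureModel
    receptor: StructureModel
    binder_chain: str
    receptor_chain: str
    motif_range: tuple[int, int]
    reference_range: tuple[int, int]
    rotation_deg: float
    axis: np.ndarray
    pivot: np.ndarray
    clash_count: int
    interface_pairs: list[tuple[int, int, float]]
    seed: int


def _atom_row(chain, resnum, resname, name, element, xyz, occ, b):
    return {
        "chain": chain, "resnum": resnum, "icode": "", "resname": resname,
        "atomname": name, "element": element,
        "x": xyz[0], "y": xyz[1], "z": xyz[2],
        "occupancy": occ, "bfactor": b, "altloc": "",
        "het": False, "water": False,
    }


def gen_toy_complex(
    seed: int = 0,
    motif_rotation_deg: float = 25.0,
    clash_count_target: int = 5,
    interface_distance: float = 3.5,
    n_background: int = 10,
) -> ToyComplex:
    """Build a toy receptor/binder complex with known geometric truths.

    The binder (chain B) is a 20-residue pseudo-C-alpha chain; residues
    15-20 form the cap motif, placed 10 A from a rotation axis through the
    last reference residue.  The bound pose rotates the motif by exactly
    ``motif_rotation_deg`` about that axis.  The receptor (chain R) carries
    ``clash_count_target`` atoms 1.5 A from distinct un-rotated motif
    atoms, three interface atoms at ``interface_distance`` from reference
    residues, and ``n_background`` distant atoms.
    """
    if not 0.0 <= motif_rotation_deg < 180.0:
        raise ValueError("motif_rotation_deg must be in [0, 180)")
    if not 0 <= clash_count_target <= 6:
        raise ValueError("clash_count_target must be in 0..6 (one per motif atom)")
    rng = _rng("toy_complex", seed)

    spacing = 3.8  # pseudo-Calpha spacing, A
    n_ref, n_motif = 14, 6
    # zig-zag (non-collinear) chain so rigid-body fits are well conditioned
    ref_positions = [
        np.array([i * spacing, 1.2 * (i % 2), 0.0]) for i in range(n_ref)
    ]
    pivot = ref_positions[-1]
    axis = np.array([0.0, 0.0, 1.0])

    radius = 10.0
    phis = np.deg2rad(20.0 * np.arange(n_motif))
    motif_unrot = [
        pivot + np.array([radius * np.cos(p), radius * np.sin(p), 2.5 * k])
        for k, p in enumerate(phis)
    ]
    theta = np.deg2rad(motif_rotation_deg)
    rot = np.array(
        [
            [np.cos(theta), -np.sin(theta), 0.0],
            [np.sin(theta), np.cos(theta), 0.0],
            [0.0, 0.0, 1.0],
        ]
    )
    motif_rot = [pivot + rot @ (m - pivot) for m in motif_unrot]

    def binder_rows(motif_positions):
        rows = []
        for i, pos in enumerate(ref_positions, start=1):
            rows.append(_atom_row("B", i, "GLY", "CA", "C", pos, 1.0, 47.0))
        for k, pos in enumerate(motif_positions, start=n_ref + 1):
            rows.append(_atom_row("B", k, "GLY", "CA", "C", pos, 1.0, 75.0))
        return rows

    receptor_rows = []
    resnum = 101
    for k in range(clash_count_target):
        direction = np.array([np.cos(phis[k]), np.sin(phis[k]), 0.0])
        receptor_rows.append(
            _atom_row("R", resnum, "GLY", "CA", "C", motif_unrot[k] + 1.5 * direction, 1.0, 30.0)
        )
        resnum += 1
    interface_pairs = []
    for b_res in (3, 6, 9):
        pos = ref_positions[b_res - 1] + np.array([0.0, interface_distance, 0.0])
        receptor_rows.append(_atom_row("R", resnum, "GLY", "CA", "C", pos, 1.0, 30.0))
        interface_pairs.append((resnum, b_res, interface_distance))
        resnum += 1
    for _ in range(n_background):
        pos = np.array([rng.uniform(0, 60), rng.uniform(-40, -30), rng.uniform(-5, 5)])
        receptor_rows.append(_atom_row("R", resnum, "GLY", "CA", "C", pos, 1.0, 30.0))
        resnum += 1

    def build(rows, title):
        return StructureModel(
            atoms=pd.DataFrame(rows, columns=ATOM_COLUMNS), title=title,
            meta={"seed": seed, "motif_rotation_deg": motif_rotation_deg},
        )

    bound = build(receptor_rows + binder_rows(motif_rot),
                  f"synthetic toy complex seed={seed} rotation={motif_rotation_deg}")
    apo = build(binder_rows(motif_unrot),
                f"synthetic toy apo binder seed={seed}")
    receptor = build(receptor_rows, f"synthetic toy receptor seed={seed}")
    return ToyComplex(
        bound=bound, apo_binder=apo, receptor=receptor,
        binder_chain="B", receptor_chain="R",
        motif_range=(n_ref + 1, n_ref + n_motif),
        reference_range=(1, n_ref),
        rotation_deg=motif_rotation_deg,
        axis=axis, pivot=pivot,
        clash_count=clash_count_target,
        interface_pairs=interface_pairs,
        seed=seed,
    )
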