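"""Seeded generators emulating every wet-lab input of the analysis chain.

Each generator draws from an explicit scenario object whose defaults mirror
the studied F-plasmid system: an AT-rich (73%) promoter carrying three
direct-orientation CTTTGC hexamers at 13-bp intervals plus two inverted
half-sites (one perfect, one 2-mismatch degenerate) forming overlapping
inverted repeats with 28- and 27-bp spacers; SPR sensorgrams obeying 1:1
Langmuir kinetics with a mass-proportional response and three dimers bound
at saturation; EMSA/MST titrations following Hill or ligand-depletion
isotherms; two-state van't Hoff melt curves; and coarse CA trajectories
with a rigid core plus a high-fluctuation winged-HTH-like loop.

All randomness flows through explicit integer seeds; equal scenario + seed
gives bit-identical output.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqIO import write as seqio_write
from Bio.SeqRecord import SeqRecord

from . import binding, motifs, thermal
from .binding import BindingIsotherm, KineticParams, Sensorgram
from .flexibility import Trajectory
from .thermal import MeltBaselines, MeltCurve

__all__ = [
    "PromoterElement",
    "PromoterArchitecture",
    "SprScenario",
    "TitrationScenario",
    "MeltScenario",
    "TrajectoryScenario",
    "default_f_architecture",
    "default_spr_scenario",
    "default_emsa_scenario",
    "default_mst_scenario",
    "default_parb_emsa_scenario",
    "default_melt_scenario",
    "default_melt_conditions",
    "default_trajectory_scenario",
    "wing_marker_trajectory_scenario",
    "build_promoter_sequence",
    "simulate_sensorgrams",
    "spr_rmax_true",
    "simulate_isotherm",
    "simulate_melt_curve",
    "simulate_trajectory",
    "write_promoter_fasta",
    "write_sensorgrams_csv",
    "write_isotherm_csv",
    "write_trajectory_csv",
    "read_trajectory_csv",
]

DNA_MW_PER_BP = 660.0  # Da per duplex base pair
PARA_MONOMER_MW = 44_000.0  # Da, configurable convention for the analyte


# ---------------------------------------------------------------------------
# Scenario types


@dataclass(frozen=True)
class PromoterElement:
    """One embedded binding motif: sequence as read 5'->3' on its strand."""

    sequence: str
    strand: Literal["+", "-"]
    gap_to_previous: int
    name: str = ""


@dataclass(frozen=True)
class PromoterArchitecture:
    """Layout of hexamer motifs embedded in an AT-rich background."""

    elements: tuple[PromoterElement, ...]
    motif_length: int = 6
    background_at_fraction: float = 0.73
    flank_left: int = 30
    flank_right: int = 28
    consensus: str = "CTTTGC"

    def __post_init__(self) -> None:
        if not 0.0 <= self.background_at_fraction <= 1.0:
            raise ValueError("AT fraction must be in [0, 1]")
        if self.flank_left < 0 or self.flank_right < 0:
            raise ValueError("flanks must be >= 0")
        for el in self.elements:
            if len(el.sequence) != self.motif_length:
                raise ValueError(
                    f"element {el.name or el.sequence!r} has length "
                    f"{len(el.sequence)}, expected {self.motif_length}"
                )
            if el.gap_to_previous < 0:
                raise ValueError("gaps must be >= 0")

    @property
    def length(self) -> int:
        core = sum(el.gap_to_previous + self.motif_length for el in self.elements)
        return self.flank_left + core + self.flank_right


@dataclass(frozen=True)
class SprScenario:
    """Ground truth for a dose-response SPR series.

    The saturation response encodes the binding stoichiometry through the
    mass proportionality of the SPR signal::

        Rmax_true = dimers * 2 * (MW_analyte / (bp * MW_per_bp)) * R_L
    """

    true_dimers_bound: int = 3
    mw_analyte: float = PARA_MONOMER_MW
    bp_ligand: int = 136
    mw_per_bp: float = DNA_MW_PER_BP
    rl_immobilized: float = 300.0  # RU
    ka_true: float = 1.0e4  # M^-1 s^-1
    kd_true: float = 1.0e-3  # s^-1
    concentrations: tuple[float, ...] = (
        5e-8,
        1e-7,
        2.5e-7,
        5e-7,
        1e-6,
        2e-6,
        4.5e-6,
    )  # M, the 0.05-4.5 uM injection series
    t_assoc: float = 180.0  # s
    t_dissoc: float = 180.0  # s
    t_step: float = 1.0  # s
    noise_sd: float = 2.0  # RU
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_dimers_bound < 0:
            raise ValueError("true_dimers_bound must be >= 0")
        if min(self.mw_analyte, self.mw_per_bp, self.rl_immobilized) <= 0:
            raise ValueError("masses and RU must be positive")
        if self.bp_ligand <= 0:
            raise ValueError("ligand length must be positive")
        if self.ka_true <= 0 or self.kd_true <= 0:
            raise ValueError("rates must be positive")
        if self.t_assoc <= 0 or self.t_dissoc <= 0 or self.t_step <= 0:
            raise ValueError("durations must be positive")
        if np.any(np.diff(self.concentrations) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def mw_ligand(self) -> float:
        return self.bp_ligand * self.mw_per_bp


@dataclass(frozen=True)
class TitrationScenario:
    """Ground truth for an equilibrium fraction-bound titration."""

    model_kind: Literal["hill", "depletion"] = "hill"
    kd_true: float = 85.0  # nM
    hill_h_true: float = 3.0
    probe_conc: float = 15.0  # nM
    protein_concs: tuple[float, ...] = tuple(np.geomspace(4.0, 30_000.0, 13))
    noise_sd: float = 0.02  # fraction-bound units
    seed: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        if self.model_kind not in ("hill", "depletion"):
            raise ValueError(f"unknown model_kind {self.model_kind!r}")
        if self.probe_conc <= 0:
            raise ValueError("probe concentration must be positive")
        if self.kd_true <= 0:
            raise ValueError("kd_true must be positive")
        if self.model_kind == "hill" and self.hill_h_true < 1:
            raise ValueError("hill_h_true must be >= 1 for the hill model")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class MeltScenario:
    """Ground truth for a two-state nanoDSF melt curve."""

    tm_true: float = 44.5  # deg C
    dH_vant_hoff: float = 300.0  # kJ/mol
    baselines: MeltBaselines = field(default_factory=MeltBaselines)
    t_range: tuple[float, float] = (25.0, 65.0)
    t_step: float = 0.1
    noise_sd: float = 0.0  # ratio units
    channel_scale: float = 5000.0  # arbitrary fluorescence units for f330
    seed: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        lo, hi = self.t_range
        if lo >= hi:
            raise ValueError("t_range must be ascending")
        if self.t_step <= 0:
            raise ValueError("t_step must be positive")
        if not lo < self.tm_true < hi:
            raise ValueError("tm_true must lie inside t_range")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class TrajectoryScenario:
    """Rigid-core-plus-flexible-loop CA trajectory parameters.

    ``loop_interval`` is an inclusive 1-based residue range with elevated
    isotropic fluctuation (``loop_sigma`` per axis); an optional marker
    residue drifts linearly by ``marker_displacement`` between the first
    and last frame, mimicking a large winged-HTH excursion.
    """

    n_residues: int = 120
    n_frames: int = 400
    core_sigma: float = 0.5  # Angstrom per axis
    loop_interval: tuple[int, int] = (40, 100)
    loop_sigma: float = 2.0  # Angstrom per axis
    marker_residue: int | None = None
    marker_displacement: float = 0.0  # Angstrom
    residue_mass: float = 110.0  # Da, average residue mass for CA-only chains
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 3:
            raise ValueError("need at least 3 residues")
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")
        if self.core_sigma < 0 or self.loop_sigma < 0:
            raise ValueError("sigmas must be >= 0")
        lo, hi = self.loop_interval
        if not (1 <= lo <= hi <= self.n_residues):
            raise ValueError("loop_interval must lie inside [1, n_residues]")
        if self.marker_residue is not None and not (
            1 <= self.marker_residue <= self.n_residues
        ):
            raise ValueError("marker_residue outside the chain")


# ---------------------------------------------------------------------------
# Default scenarios


def default_f_architecture() -> PromoterArchitecture:
    """The F-plasmid promoter layout: motifs #1, #2, #3 in direct orientation
    with 13-bp gaps, the degenerate #2' (tcTTGC, read on the minus strand)
    27 bp downstream of #2, and the perfect #4 inverted 28 bp downstream of
    #3.  Flanks sized so the built fragment is 136 bp, the SPR probe length.
    """
    return PromoterArchitecture(
        elements=(
            PromoterElement("CTTTGC", "+", 0, name="1"),
            PromoterElement("CTTTGC", "+", 13, name="2"),
            PromoterElement("CTTTGC", "+", 13, name="3"),
            PromoterElement("TCTTGC", "-", 8, name="2p"),
            PromoterElement("CTTTGC", "-", 14, name="4"),
        )
    )


def default_spr_scenario(seed: int = 0, **overrides) -> SprScenario:
    """Three dimers on the 136-bp promoter probe at 300 RU immobilized."""
    return replace(SprScenario(seed=seed), **overrides)


def default_emsa_scenario(seed: int = 0, **overrides) -> TitrationScenario:
    """Cooperative gel-shift titration: KD 85 nM, Hill h 3, 15 nM probe."""
    return replace(TitrationScenario(seed=seed, label="emsa"), **overrides)


def default_mst_scenario(seed: int = 0, **overrides) -> TitrationScenario:
    """Thermophoresis titration: KD 140 nM, non-cooperative, 25 nM probe,
    protein 3.6 nM - 60 uM."""
    return replace(
        TitrationScenario(
            model_kind="hill",
            kd_true=140.0,
            hill_h_true=1.0,
            probe_conc=25.0,
            protein_concs=tuple(np.geomspace(3.6, 60_000.0, 16)),
            seed=seed,
            label="mst",
        ),
        **overrides,
    )


def default_parb_emsa_scenario(seed: int = 0, **overrides) -> TitrationScenario:
    """ParB-stimulated binding: KD ~10 nM, close to the 15 nM probe, so the
    ligand-depletion model applies."""
    return replace(
        TitrationScenario(
            model_kind="depletion",
            kd_true=10.0,
            hill_h_true=1.0,
            probe_conc=15.0,
            protein_concs=tuple(np.geomspace(2.0, 2000.0, 13)),
            seed=seed,
            label="emsa+parb",
        ),
        **overrides,
    )


def default_melt_conditions() -> dict[str, float]:
    """Condition -> Tm (deg C) map for the apo/DNA/ADP melting comparisons."""
    return {"apo": 44.5, "dna": 45.1, "adp": 46.1, "dna_adp": 45.8}


def default_melt_scenario(
    condition: str = "apo", seed: int = 0, **overrides
) -> MeltScenario:
    conditions = default_melt_conditions()
    if condition not in conditions:
        raise ValueError(f"unknown condition {condition!r}; known: {sorted(conditions)}")
    return replace(
        MeltScenario(tm_true=conditions[condition], seed=seed, label=condition),
        **overrides,
    )


def default_trajectory_scenario(seed: int = 0, **overrides) -> TrajectoryScenario:
    return replace(TrajectoryScenario(seed=seed), **overrides)


def wing_marker_trajectory_scenario(seed: int = 0, **overrides) -> TrajectoryScenario:
    """Scenario with a marker residue at position 75 drifting 30 Angstrom,
    emulating the large wing-tip excursion of the DNA-binding domain."""
    return replace(
        TrajectoryScenario(marker_residue=75, marker_displacement=30.0, seed=seed),
        **overrides,
    )


# ---------------------------------------------------------------------------
# Generators


def _element_layout(arch: PromoterArchitecture) -> list[tuple[PromoterElement, int]]:
    """Plus-strand start coordinate of each element; errors on collisions."""
    layout: list[tuple[PromoterElement, int]] = []
    pos = arch.flank_left
    prev_end: int | None = None
    prev_el: PromoterElement | None = None
    for el in arch.elements:
        start = pos + el.gap_to_previous
        if prev_end is not None and start < prev_end:
            raise ValueError(
                f"elements {prev_el.name or prev_el.sequence!r} and "
                f"{el.name or el.sequence!r} overlap at position {start}"
            )
        layout.append((el, start))
        pos = start + arch.motif_length
        prev_end = pos
        prev_el = el
    return layout


def build_promoter_sequence(
    arch: PromoterArchitecture, seed: int, max_attempts: int = 200
) -> tuple[str, pd.DataFrame]:
    """Build a promoter sequence embedding the architecture's motifs in an
    i.i.d. AT-rich background, together with its motif truth table.

    Minus-strand elements are embedded as reverse complements; the truth
    table records each element's 0-based start, strand, the site as read on
    its strand, and its mismatch count versus the consensus.  The background
    is resampled (bounded, seeded attempts) until it introduces no exact
    consensus match beyond the truth table, so exact-hit counts reflect the
    architecture for every seed.
    """
    layout = _element_layout(arch)
    rng = np.random.default_rng(seed)
    at = arch.background_at_fraction
    probs = [at / 2, (1 - at) / 2, (1 - at) / 2, at / 2]  # A, C, G, T
    total_len = arch.length

    embedded: dict[int, str] = {}
    records = []
    for el, start in layout:
        plus_seq = (
            el.sequence.upper()
            if el.strand == "+"
            else motifs.reverse_complement(el.sequence.upper())
        )
        for k, b in enumerate(plus_seq):
            embedded[start + k] = b
        records.append(
            {
                "name": el.name or el.sequence,
                "start": start,
                "strand": el.strand,
                "sequence": el.sequence.upper(),
                "mismatches": motifs.hamming(el.sequence, arch.consensus),
            }
        )
    truth = pd.DataFrame.from_records(records)
    exact_truth = {
        (int(r.start), r.strand) for r in truth.itertuples() if r.mismatches == 0
    }

    background_idx = [i for i in range(total_len) if i not in embedded]
    for _ in range(max_attempts):
        chars = np.empty(total_len, dtype="<U1")
        for i, b in embedded.items():
            chars[i] = b
        draw = rng.choice(list("ACGT"), size=len(background_idx), p=probs)
        chars[background_idx] = draw
        seq = "".join(chars)
        exact_hits = {
            (h.start, h.strand) for h in motifs.scan_motifs(seq, arch.consensus, 0)
        }
        if exact_hits == exact_truth:
            return seq, truth
    raise RuntimeError(
        "could not draw a background free of spurious consensus matches "
        f"in {max_attempts} attempts"
    )


def spr_rmax_true(s: SprScenario) -> float:
    """Saturation response implied by the scenario's true stoichiometry."""
    return (
        s.true_dimers_bound * 2.0 * (s.mw_analyte / s.mw_ligand) * s.rl_immobilized
    )


def simulate_sensorgrams(s: SprScenario, seed: int | None = None) -> list[Sensorgram]:
    """Simulate the dose-response injection series of the scenario.

    Each curve follows the closed-form 1:1 Langmuir model with the
    scenario's true rates and the stoichiometry-implied Rmax, plus i.i.d.
    Gaussian noise of ``noise_sd`` RU.
    """
    rng = np.random.default_rng(s.seed if seed is None else seed)
    rmax = spr_rmax_true(s)
    times = np.arange(0.0, s.t_assoc + s.t_dissoc + s.t_step / 2, s.t_step)
    out: list[Sensorgram] = []
    for conc in s.concentrations:
        if rmax > 0:
            resp = binding.langmuir_forward(
                KineticParams(s.ka_true, s.kd_true, rmax),
                conc,
                times,
                t_inject=0.0,
                t_stop=s.t_assoc,
            )
        else:
            resp = np.zeros_like(times)
        if s.noise_sd > 0:
            resp = resp + rng.normal(0.0, s.noise_sd, size=times.shape)
        out.append(
            Sensorgram(times=times.copy(), response=resp, conc=conc, t_stop=s.t_assoc)
        )
    return out


def simulate_isotherm(s: TitrationScenario, seed: int | None = None) -> BindingIsotherm:
    """Simulate a fraction-bound titration from the scenario's forward model,
    with additive Gaussian noise clipped into [0, 1]."""
    rng = np.random.default_rng(s.seed if seed is None else seed)
    p = np.asarray(s.protein_concs, dtype=float)
    if s.model_kind == "hill":
        theta = binding.hill_model(p, s.kd_true, s.hill_h_true)
    else:
        theta = binding.depletion_model(p, s.probe_conc, s.kd_true)
    if s.noise_sd > 0:
        theta = theta + rng.normal(0.0, s.noise_sd, size=p.shape)
    theta = np.clip(theta, 0.0, 1.0)
    return BindingIsotherm(
        conc_nM=p, fraction_bound=theta, probe_conc_nM=s.probe_conc, label=s.label
    )


def simulate_melt_curve(s: MeltScenario, seed: int | None = None) -> MeltCurve:
    """Simulate a dual-wavelength melt curve of the two-state model.

    The 330-nm channel carries a flat scale; the 350-nm channel carries the
    model ratio; per-channel Gaussian noise of ``noise_sd * scale / sqrt(2)``
    propagates to about ``noise_sd`` on the ratio near 1.
    """
    rng = np.random.default_rng(s.seed if seed is None else seed)
    lo, hi = s.t_range
    t = np.arange(lo, hi + s.t_step / 2, s.t_step)
    ratio = thermal.two_state_ratio(t, s.tm_true, s.dH_vant_hoff, s.baselines)
    f330 = np.full_like(t, s.channel_scale)
    f350 = s.channel_scale * ratio
    if s.noise_sd > 0:
        ch_sd = s.noise_sd * s.channel_scale / math.sqrt(2.0)
        f330 = f330 + rng.normal(0.0, ch_sd, size=t.shape)
        f350 = f350 + rng.normal(0.0, ch_sd, size=t.shape)
    return MeltCurve(temperatures=t, f330=f330, f350=f350, label=s.label)


def _reference_chain(n_residues: int) -> np.ndarray:
    """Deterministic coarse helical CA chain (non-collinear reference)."""
    i = np.arange(n_residues, dtype=float)
    theta = np.radians(100.0) * i
    return np.column_stack(
        [2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * i]
    )


def simulate_trajectory(s: TrajectoryScenario, seed: int | None = None) -> Trajectory:
    """Simulate a CA trajectory: reference chain + per-residue isotropic
    Gaussian perturbations, with elevated sigma inside the loop interval and
    an optional linear marker drift between first and last frame."""
    rng = np.random.default_rng(s.seed if seed is None else seed)
    ref = _reference_chain(s.n_residues)
    residue_ids = np.arange(1, s.n_residues + 1)
    sigma = np.full(s.n_residues, s.core_sigma)
    lo, hi = s.loop_interval
    sigma[(residue_ids >= lo) & (residue_ids <= hi)] = s.loop_sigma
    coords = ref[None, :, :] + rng.normal(
        0.0, 1.0, size=(s.n_frames, s.n_residues, 3)
    ) * sigma[None, :, None]
    if s.marker_residue is not None and s.marker_displacement != 0.0:
        direction = np.array([1.0, 1.0, 1.0]) / math.sqrt(3.0)
        frac = np.arange(s.n_frames) / (s.n_frames - 1)
        coords[:, s.marker_residue - 1, :] += (
            s.marker_displacement * frac[:, None] * direction[None, :]
        )
    return Trajectory(
        coords=coords,
        residue_ids=residue_ids,
        masses=np.full(s.n_residues, s.residue_mass),
    )


# ---------------------------------------------------------------------------
# Writers / readers (plain-text interchange formats)


def write_promoter_fasta(
    seq: str, path: str | Path, seq_id: str = "PparAB_synthetic"
) -> None:
    """Write the promoter as 60-column-wrapped FASTA."""
    rec = SeqRecord(Seq(seq), id=seq_id, description="")
    with open(path, "w") as fh:
        seqio_write([rec], fh, "fasta")


def write_sensorgrams_csv(sensorgrams: Sequence[Sensorgram], path: str | Path) -> None:
    """Long-format CSV: time_s, response_RU, conc_M, phase."""
    frames = []
    for sg in sensorgrams:
        phase = np.where(sg.times <= sg.t_stop, "association", "dissociation")
        frames.append(
            pd.DataFrame(
                {
                    "time_s": sg.times,
                    "response_RU": sg.response,
                    "conc_M": sg.conc,
                    "phase": phase,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_isotherm_csv(iso: BindingIsotherm, path: str | Path) -> None:
    pd.DataFrame(
        {"conc_nM": iso.conc_nM, "fraction_bound": iso.fraction_bound}
    ).to_csv(path, index=False)


def write_trajectory_csv(traj: Trajectory, path: str | Path) -> None:
    """Long-format CSV: frame, residue, x, y, z, mass (Angstrom, Da)."""
    n_frames, n_atoms, _ = traj.coords.shape
    frame_col = np.repeat(np.arange(n_frames), n_atoms)
    res_col = np.tile(traj.residue_ids, n_frames)
    mass_col = np.tile(traj.masses, n_frames)
    flat = traj.coords.reshape(-1, 3)
    pd.DataFrame(
        {
            "frame": frame_col,
            "residue": res_col,
            "x": flat[:, 0],
            "y": flat[:, 1],
            "z": flat[:, 2],
            "mass": mass_col,
        }
    ).to_csv(path, index=False)


def read_trajectory_csv(path: str | Path) -> Trajectory:
    df = pd.read_csv(path).sort_values(["frame", "residue"])
    frames = df["frame"].unique()
    residues = df[df["frame"] == frames[0]]["residue"].to_numpy()
    masses = df[df["frame"] == frames[0]]["mass"].to_numpy(dtype=float)
    coords = df[["x", "y", "z"]].to_numpy().reshape(len(frames), len(residues), 3)
    return Trajectory(coords=coords, residue_ids=residues, masses=masses)


def scenario_to_json(scenario, path: str | Path) -> None:
    """Serialize any scenario dataclass to JSON (kind-tagged)."""
    payload = asdict(scenario)
    payload["kind"] = type(scenario).__name__
    for k, v in payload.items():
        if isinstance(v, tuple):
            payload[k] = list(v)
    Path(path).write_text(json.dumps(payload, indent=2, default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
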