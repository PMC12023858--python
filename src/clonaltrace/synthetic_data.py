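"""Synthetic data generators: tracer-flux simulator and expression matrices.

Two generators feed the pipeline with inputs whose ground truth is known:

* a stage-stepped compartmental label-flux simulator that emulates the
  field design — three treatments (parent-labelled PL, rhizosphere-
  labelled RL, unlabelled control) × four growth stages × replicated
  organ measurements — with label mass conserved exactly across
  compartments at every stage;
* an expression/trait generator that plants trait-correlated genes and
  differentially expressed genes into a lognormal FPKM background, with
  truth labels returned for recall tests.

Label moves between compartments via one row-stochastic transfer matrix
per stage transition; whatever a row does not send elsewhere stays put.
Measurement noise has two parts: multiplicative lognormal (unit mean)
noise on the tracer-derived atom% excess and on biomass, representing
fragment-to-fragment biological variability, plus a small additive
Gaussian error on atom% itself, representing isotope-ratio instrument
precision. The additive term lets measured atom% dip below background in
weakly labelled organs, which is what produces the (flagged) negative
Ndff values real datasets contain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .isotope_core import DEFAULT_BACKGROUND_ATOM_PCT, STAGE_ORDER, TracerSpec

__all__ = [
    "COMPARTMENTS",
    "FragmentModel",
    "ExprSimConfig",
    "GroundTruth",
    "default_model",
    "simulate_fragment",
    "ground_truth",
    "make_traits",
    "generate_expression",
    "DEFAULT_TRACER",
]

#: Compartment order used by every transfer matrix.
COMPARTMENTS = ("source_pool", "leaf", "culm", "rhizome", "shoot", "nascent_leaf", "loss")
_PLANT_ORGANS = ("leaf", "culm", "rhizome", "shoot", "nascent_leaf")
_OFFSPRING = ("shoot", "nascent_leaf")

#: Field tracer: 10 ml of doubly labelled ammonium nitrate solution,
#: 50 mg N ml⁻¹ at 30.14 atom% → 150.7 mg labelled ¹⁵N per fragment.
DEFAULT_TRACER = TracerSpec(volume_ml=10.0, n_conc_mg_per_ml=50.0, atom_pct=30.14)

FlowSpec = dict[str, dict[str, float]]


def _compile_matrix(flows: FlowSpec) -> np.ndarray:
    """Build a row-stochastic matrix from sparse outflow fractions.

    ``flows[src][dst]`` is the fraction of ``src``'s label moving to
    ``dst`` during the transition; the remainder stays in ``src``.
    """
    n = len(COMPARTMENTS)
    idx = {c: i for i, c in enumerate(COMPARTMENTS)}
    mat = np.zeros((n, n))
    for src, outs in flows.items():
        if src not in idx:
            raise ValueError(f"unknown compartment {src!r}")
        total = 0.0
        for dst, frac in outs.items():
            if dst not in idx:
                raise ValueError(f"unknown compartment {dst!r}")
            if not 0 <= frac <= 1:
                raise ValueError(f"flow {src}->{dst}={frac} outside [0, 1]")
            mat[idx[src], idx[dst]] += frac
            total += frac
        if total > 1 + 1e-12:
            raise ValueError(f"outflows from {src!r} sum to {total} > 1")
        mat[idx[src], idx[src]] = 1.0 - total
    for i, c in enumerate(COMPARTMENTS):
        if not mat[i].any():
            mat[i, i] = 1.0
    if not np.allclose(mat.sum(axis=1), 1.0, rtol=0, atol=1e-12):
        raise ValueError("transfer matrix rows must sum to 1")
    return mat


@dataclass
class FragmentModel:
    """Parameters of the stage-stepped clonal-fragment tracer simulator.

    Parameters
    ----------
    transfer : list of flow dicts
        One sparse outflow spec per stage transition (label application →
        ES, ES → PS, PS → BS, BS → LS); compiled to row-stochastic
        matrices over :data:`COMPARTMENTS`.
    injection : dict
        Treatment → compartment receiving the dose (PL → culm via cavity
        injection, RL → source_pool, the rhizosphere soil).
    dose_mg : float
        Labelled ¹⁵N applied per fragment, mg.
    tn_conc, biomass : dict
        Per (stage, organ) total-N concentration (mg kg⁻¹) and biomass
        (kg) trajectories; the nascent leaf exists only at LS.
    noise_cv, biomass_cv : float
        Coefficients of variation of the multiplicative lognormal
        biological noise on the tracer-derived atom% excess and on
        biomass.
    atom_noise_sd : float
        SD of the additive Gaussian instrument error on atom%, in atom%
        units (isotope-ratio measurement precision).
    """

    transfer: list[FlowSpec]
    injection: dict[str, str] = field(
        default_factory=lambda: {"PL": "culm", "RL": "source_pool"}
    )
    dose_mg: float = 150.7
    tracer: TracerSpec = DEFAULT_TRACER
    background_atom_pct: float = DEFAULT_BACKGROUND_ATOM_PCT
    tn_conc: dict[tuple[str, str], float] = field(default_factory=dict)
    biomass: dict[tuple[str, str], float] = field(default_factory=dict)
    noise_cv: float = 0.10
    biomass_cv: float = 0.10
    atom_noise_sd: float = 0.002
    n_replicates: int = 3
    seed: int = 0

    def matrices(self) -> list[np.ndarray]:
        if len(self.transfer) != len(STAGE_ORDER):
            raise ValueError(
                f"need {len(STAGE_ORDER)} transfer specs, got {len(self.transfer)}"
            )
        return [_compile_matrix(f) for f in self.transfer]

    def organs_at(self, stage: str) -> tuple[str, ...]:
        return tuple(o for o in _PLANT_ORGANS if (stage, o) in self.biomass)


def default_model(seed: int = 0, **overrides) -> FragmentModel:
    """The bundled synthetic field scenario.

    Transfer fractions are hand-designed so the parent-vs-rhizome supply
    split to the offspring ramet sweeps from roughly 7:3 at ES through
    near-parity at PS/BS to roughly 3:7 at LS, with a ~30% net withdrawal
    of offspring label between BS and LS under parent labelling. All
    numbers are synthetic: they reproduce a qualitative pattern, not any
    measured dataset.
    """
    transfer: list[FlowSpec] = [
        # label application → ES: parent culm unloads to the new shoot;
        # most soil label is still resident in the rhizosphere pool
        {
            "source_pool": {"rhizome": 0.05, "shoot": 0.077, "culm": 0.02,
                            "leaf": 0.01, "loss": 0.05},
            "culm": {"shoot": 0.18, "leaf": 0.07, "rhizome": 0.04, "loss": 0.06},
            "rhizome": {"shoot": 0.10, "culm": 0.05},
            "leaf": {"culm": 0.04},
        },
        # ES → PS: peak transport into the elongating shoot; rhizome-root
        # uptake of soil label catches up with the parent supply
        {
            "source_pool": {"rhizome": 0.08, "shoot": 0.295, "culm": 0.02,
                            "loss": 0.06},
            "culm": {"shoot": 0.22, "leaf": 0.05, "loss": 0.05},
            "rhizome": {"shoot": 0.30, "culm": 0.05},
            "leaf": {"culm": 0.08},
            "shoot": {"loss": 0.02},
        },
        # PS → BS: transport slows, shoot keeps accumulating from both sources
        {
            "source_pool": {"rhizome": 0.05, "shoot": 0.10, "loss": 0.05},
            "culm": {"shoot": 0.12, "leaf": 0.06, "loss": 0.04},
            "rhizome": {"shoot": 0.15, "culm": 0.04},
            "shoot": {"loss": 0.03},
        },
        # BS → LS: leafing (the longest interval); the remaining soil label
        # is taken up, while part of the offspring's label is withdrawn into
        # the parent leaf and rhizome and part moves into the nascent leaves
        {
            "source_pool": {"rhizome": 0.05, "shoot": 0.62, "loss": 0.05},
            "culm": {"leaf": 0.10, "shoot": 0.04, "loss": 0.03},
            "rhizome": {"shoot": 0.30},
            "shoot": {"nascent_leaf": 0.12, "leaf": 0.304, "rhizome": 0.10,
                      "loss": 0.04},
        },
    ]
    # total-N concentration (mg kg⁻¹) and biomass (kg) trajectories;
    # the offspring shoot grows by two orders of magnitude while its N
    # concentration is diluted, the parent organs are roughly static
    tn_conc: dict[tuple[str, str], float] = {}
    biomass: dict[tuple[str, str], float] = {}
    organ_tn = {"leaf": 20000.0, "culm": 4500.0, "rhizome": 3200.0}
    organ_bm = {"leaf": 1.2, "culm": 9.0, "rhizome": 2.0}
    shoot_tn = {"ES": 9000.0, "PS": 6500.0, "BS": 5000.0, "LS": 4000.0}
    shoot_bm = {"ES": 0.3, "PS": 4.0, "BS": 9.0, "LS": 14.0}
    for stage in STAGE_ORDER:
        for organ, tn in organ_tn.items():
            tn_conc[(stage, organ)] = tn
            biomass[(stage, organ)] = organ_bm[organ]
        tn_conc[(stage, "shoot")] = shoot_tn[stage]
        biomass[(stage, "shoot")] = shoot_bm[stage]
    tn_conc[("LS", "nascent_leaf")] = 24000.0
    biomass[("LS", "nascent_leaf")] = 0.4
    return FragmentModel(
        transfer=transfer, tn_conc=tn_conc, biomass=biomass, seed=seed, **overrides
    )


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


def _label_states(model: FragmentModel) -> dict[str, np.ndarray]:
    """Noise-free label mass (mg) per compartment at each stage, per treatment.

    Returns treatment → array of shape (n_stages, n_compartments). Mass is
    conserved exactly: every row sums to the dose.
    """
    mats = model.matrices()
    idx = {c: i for i, c in enumerate(COMPARTMENTS)}
    states: dict[str, np.ndarray] = {}
    for treatment, compartment in model.injection.items():
        state = np.zeros(len(COMPARTMENTS))
        state[idx[compartment]] = model.dose_mg
        loss_i = idx["loss"]
        rows = []
        for mat in mats:
            state = state @ mat
            # the loss column absorbs float residue: conservation is exact
            state[loss_i] += model.dose_mg - state.sum()
            rows.append(state.copy())
        states[treatment] = np.asarray(rows)
    return states


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean multiplicative lognormal noise with the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


def simulate_fragment(model: FragmentModel) -> pd.DataFrame:
    """Simulate the full measurement table the isotope pipeline ingests.

    Label is propagated through the stage transfer matrices; each organ's
    atom% ¹⁵N is the two-pool mixture of background N and tracer-derived
    label in its total-N pool, so a noise-free run inverts exactly
    through the Ndff/content equations. The tracer-derived excess and
    the biomass get multiplicative lognormal biological noise
    (``noise_cv``, ``biomass_cv``); atom% additionally gets additive
    Gaussian instrument error (``atom_noise_sd``). Control replicates
    carry background plus instrument error only. Output is deterministic
    for a fixed seed.

    Returns a tidy table with one row per
    (treatment, stage, organ, replicate).
    """
    rng = np.random.default_rng(model.seed)
    states = _label_states(model)
    a0 = model.background_atom_pct
    c = model.tracer.atom_pct
    idx = {comp: i for i, comp in enumerate(COMPARTMENTS)}
    rows = []
    for treatment in ("PL", "RL", "control"):
        for s_i, stage in enumerate(STAGE_ORDER):
            for organ in model.organs_at(stage):
                tn = model.tn_conc[(stage, organ)]
                bm = model.biomass[(stage, organ)]
                tn_mass_mg = tn * bm  # organ total-N pool
                if treatment == "control":
                    label = 0.0
                else:
                    label = states[treatment][s_i, idx[organ]]
                    if label > tn_mass_mg:
                        raise ValueError(
                            f"label ({label:.3g} mg) exceeds the N pool of "
                            f"{organ} at {stage} ({tn_mass_mg:.3g} mg); "
                            "increase tn_conc or biomass"
                        )
                excess_true = (label / tn_mass_mg) * (c - a0)
                atom = (
                    a0
                    + excess_true
                    * _lognormal_factors(rng, model.noise_cv, model.n_replicates)
                    + (
                        rng.normal(0.0, model.atom_noise_sd, model.n_replicates)
                        if model.atom_noise_sd > 0
                        else np.zeros(model.n_replicates)
                    )
                )
                bio = bm * _lognormal_factors(
                    rng, model.biomass_cv, model.n_replicates
                )
                for rep in range(1, model.n_replicates + 1):
                    rows.append(
                        {
                            "treatment": treatment,
                            "stage": stage,
                            "organ": organ,
                            "replicate": rep,
                            "atom_pct_15N": float(
                                np.clip(atom[rep - 1], 0.0, 100.0)
                            ),
                            "tn_conc_mg_per_kg": tn,
                            "biomass_kg": bio[rep - 1],
                        }
                    )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class GroundTruth:
    """Noise-free analytic truth for a simulated scenario."""

    states: dict[str, np.ndarray]
    fate: pd.DataFrame
    contributions: pd.DataFrame
    backflow: pd.DataFrame


def ground_truth(model: FragmentModel) -> GroundTruth:
    """Analytic label propagation — the oracle for parameter-recovery tests.

    Returns the per-stage label states, the true fate panel (organ shares
    of dose, with soil-resident plus lost label pooled as ``loss``), the
    true parent/rhizome contribution split per stage, and the true
    between-stage offspring backflow under each treatment.
    """
    states = _label_states(model)
    idx = {comp: i for i, comp in enumerate(COMPARTMENTS)}
    fate_rows = []
    contrib_rows = []
    back_rows = []
    off_idx = [idx[o] for o in _OFFSPRING]
    for s_i, stage in enumerate(STAGE_ORDER):
        off = {
            t: states[t][s_i, off_idx].sum() / model.dose_mg * 100.0
            for t in states
        }
        if off["PL"] + off["RL"] > 0:
            parent = 100.0 * off["PL"] / (off["PL"] + off["RL"])
            contrib_rows.append(
                {"stage": stage, "parent_share": parent,
                 "rhizome_share": 100.0 - parent}
            )
        else:
            contrib_rows.append(
                {"stage": stage, "parent_share": np.nan, "rhizome_share": np.nan}
            )
        for treatment, traj in states.items():
            shares = {
                o: traj[s_i, idx[o]] / model.dose_mg * 100.0 for o in _PLANT_ORGANS
            }
            fate_rows.append(
                {
                    "treatment": treatment,
                    "stage": stage,
                    **shares,
                    "loss": 100.0 - sum(shares.values()),
                    "offspring_recovery": off[treatment],
                }
            )
    for treatment, traj in states.items():
        off_traj = traj[:, off_idx].sum(axis=1)
        for i in range(len(STAGE_ORDER) - 1):
            if off_traj[i] > 0:
                back_rows.append(
                    {
                        "treatment": treatment,
                        "from_stage": STAGE_ORDER[i],
                        "to_stage": STAGE_ORDER[i + 1],
                        "backflow_pct": 100.0
                        * (off_traj[i] - off_traj[i + 1])
                        / off_traj[i],
                    }
                )
    return GroundTruth(
        states=states,
        fate=pd.DataFrame(fate_rows),
        contributions=pd.DataFrame(contrib_rows),
        backflow=pd.DataFrame(back_rows),
    )


# ---------------------------------------------------------------------------
# expression / trait generator
# ---------------------------------------------------------------------------

EXPR_ORGANS = ("leaf", "culm", "rhizome", "shoot")
TRAITS = ("TN", "NH4", "NO3", "soluble_protein")


@dataclass
class ExprSimConfig:
    """Configuration of the synthetic expression/trait generator.

    ``fold_change`` is in log₂ units and shifts planted DEGs between the
    ES and PS stages in every organ; ``dispersion`` is the SD of the
    log₂-scale replicate noise; ``trait_r`` is the target correlation of
    planted trait genes with the latent physiological axis the four
    traits share.
    """

    n_genes: int = 200
    n_planted_trait_genes: int = 10
    n_planted_degs: int = 20
    fold_change: float = 3.0
    dispersion: float = 0.25
    fpkm_floor: float = 10.0
    trait_r: float = 0.95
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_planted_trait_genes + self.n_planted_degs > self.n_genes:
            raise ValueError("planted gene counts exceed n_genes")
        if self.fold_change < 0:
            raise ValueError("fold_change must be non-negative")


#: Latent N-status level per growth stage: N availability peaks during
#: the peak growth stage and declines toward leafing.
_STAGE_LEVEL = {"ES": 0.8, "PS": 3.0, "BS": 2.0, "LS": 1.4}


def make_traits(cfg: ExprSimConfig) -> tuple[pd.DataFrame, np.ndarray]:
    """Physiological trait table over (organ, stage) cells.

    The four N-status traits (total N, ammonium, nitrate, soluble
    protein) co-vary along one latent physiological axis with a strong
    stage profile (N status peaks at the peak growth stage), as they do
    in real tissue panels; planted trait genes track the same axis and
    therefore also differ between early and peak stages. Returns the
    tidy trait table and the latent vector (one value per cell).
    """
    rng = np.random.default_rng(cfg.seed + 1)
    organ_offset = {o: rng.uniform(-0.3, 0.3) for o in EXPR_ORGANS}
    cells = [(o, s) for o in EXPR_ORGANS for s in STAGE_ORDER]
    latent = np.array(
        [
            _STAGE_LEVEL[s] + organ_offset[o] + rng.normal(0.0, 0.15)
            for o, s in cells
        ]
    )
    rows = []
    scales = {"TN": 8000.0, "NH4": 120.0, "NO3": 300.0, "soluble_protein": 25.0}
    trait_vals = {}
    for trait, scale in scales.items():
        noise = rng.normal(0.0, 0.04 * latent.std(), size=len(cells))
        trait_vals[trait] = scale * (latent + noise)
    for i, (organ, stage) in enumerate(cells):
        rows.append(
            {"organ": organ, "stage": stage}
            | {t: trait_vals[t][i] for t in TRAITS}
        )
    return pd.DataFrame(rows), latent


def generate_expression(
    cfg: ExprSimConfig, traits: pd.DataFrame | None = None
) -> dict:
    """FPKM matrix with planted trait-correlated genes and planted DEGs.

    Background genes draw lognormal FPKM around gene-specific baselines;
    planted trait genes are an affine function of the latent trait axis
    plus noise calibrated to the target correlation; planted DEGs are
    shifted by ``fold_change`` log₂ units at PS relative to ES in every
    organ. Deterministic for a fixed seed.

    Returns a dict with ``fpkm`` (genes × samples), ``samples`` metadata,
    ``traits``, and ``truth`` (per-gene planted labels).
    """
    if traits is None:
        traits, latent = make_traits(cfg)
    else:
        latent = None
    rng = np.random.default_rng(cfg.seed)
    cells = [(o, s) for o in EXPR_ORGANS for s in STAGE_ORDER]
    cell_index = {c: i for i, c in enumerate(cells)}
    samples = pd.DataFrame(
        [
            {"sample": f"{o}_{s}_{r}", "organ": o, "stage": s, "replicate": r}
            for o, s in cells
            for r in range(1, cfg.n_replicates + 1)
        ]
    )
    n_samples = len(samples)
    genes = [f"gene{i:05d}" for i in range(cfg.n_genes)]
    is_trait = np.zeros(cfg.n_genes, dtype=bool)
    is_deg = np.zeros(cfg.n_genes, dtype=bool)
    is_trait[: cfg.n_planted_trait_genes] = True
    is_deg[cfg.n_planted_trait_genes : cfg.n_planted_trait_genes + cfg.n_planted_degs] = True

    if latent is None:
        # recover a latent axis from the supplied traits (their z-score mean)
        vals = traits.set_index(["organ", "stage"]).loc[cells][list(TRAITS)]
        z = (vals - vals.mean()) / vals.std(ddof=0)
        latent = z.mean(axis=1).to_numpy()

    cell_of_sample = np.array(
        [cell_index[(o, s)] for o, s in zip(samples["organ"], samples["stage"])]
    )
    log2_base = rng.uniform(2.0, 7.0, size=cfg.n_genes)
    log2_mean = np.tile(log2_base[:, None], (1, n_samples))

    # planted DEGs: PS shifted vs ES, every organ
    ps_mask = (samples["stage"] == "PS").to_numpy()
    log2_mean[np.ix_(is_deg, ps_mask)] += cfg.fold_change

    noise = rng.normal(0.0, cfg.dispersion, size=(cfg.n_genes, n_samples))
    fpkm = np.power(2.0, log2_mean + noise)

    # planted trait genes: affine in the latent axis on the FPKM scale,
    # with noise sized for the target per-cell correlation
    lat = np.asarray(latent, dtype=float)
    lat_c = lat - lat.mean()
    sd_lat = lat_c.std(ddof=0)
    for g in np.flatnonzero(is_trait):
        slope = rng.uniform(25.0, 60.0)
        intercept = rng.uniform(5.0, 15.0)
        sd_noise = slope * sd_lat * np.sqrt(1.0 / cfg.trait_r**2 - 1.0)
        cell_vals = intercept + slope * lat + rng.normal(0.0, sd_noise, size=len(lat))
        rep_noise = rng.normal(
            0.0, 0.02 * max(cell_vals.std(ddof=0), 1e-9), size=n_samples
        )
        fpkm[g] = np.clip(cell_vals[cell_of_sample] + rep_noise, 0.0, None)

    fpkm_df = pd.DataFrame(fpkm, index=genes, columns=samples["sample"])
    truth = pd.DataFrame(
        {"gene": genes, "is_trait_gene": is_trait, "is_deg": is_deg}
    )
    return {"fpkm": fpkm_df, "samples": samples, "traits": traits, "truth": truth}
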