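"""Simulation of pot experiments from an explicit plastic-root competition model.

The model behind the generator
------------------------------
Each genotype g carries an intrinsic per-plant projected root area A_g — the
area its plants express in a pure stand, where every neighbour is the same
genotype and the below-ground arms race is fully engaged.  In a binary
mixture the focal plant re-equilibrates against a *non-self* neighbour:

* the perceived competitive pressure of a non-self neighbour is discounted
  by a factor ``kappa`` < 1 (plants disengage from the arms race they run
  against their own genotype), and
* the strength of the plastic response grows with how competitive the tube
  is: the focal exponent is ``theta_k * (w*A_f + (1-w)*A_pair) / A_panel``
  (capped below 1), so large-rooted genotypes — the ones whose pure-stand
  area is most inflated by escalation — are also the most plastic.

The realized area is the geometric interpolation
``a_f = A_f**(1-theta) * (kappa*A_n)**theta`` (see :func:`plastic_root_area`);
in pure stands the neighbour is self (no discount) and the realized area is
exactly A_f.  Per-plant biomass then follows

    b = m_k * a**gamma / (1 + delta_k * a_bar_tube) * block * date * lognormal

where ``a_bar_tube`` is the tube-mean realized area, so that crowded tubes
pay a shared-resource penalty, and the root:shoot split follows the
treatment ratio rho_k.  With ``theta`` and ``delta`` positive only under
resource limitation (R-), mixtures underyield in R- only, large-rooted
genotypes lose realized area to their weaker partners, and the loss
propagates to biomass — the arms-race relaxation pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from .design import CONTROL_GENOTYPE, PLANTS_PER_POT, generate_design

PLANT_COLUMNS = [
    "tube_id", "position", "genotype_id", "shoot_biomass", "root_biomass",
    "total_biomass", "n_leaves", "n_tillers", "leaf_n",
]
TUBE_COLUMNS = ["tube_id", "root_length", "root_area"]


@dataclass
class SimulationParams:
    """Parameters of the competition simulator.

    All per-treatment entries are keyed by treatment label.  Scales:
    areas mm^2, biomass mg, root length cm, leaf N % dry mass.
    """

    theta: dict = field(default_factory=lambda: {"R+": 0.0, "R-": 0.3})
    delta: dict = field(default_factory=lambda: {"R+": 0.0, "R-": 2.5e-5})
    gamma: float = 1.0
    #: biomass scale per treatment (mg / mm^gamma); None = calibrate so that
    #: expected pure-stand tube totals hit ``target_pure_totals``
    m: dict | None = None
    rho: dict = field(default_factory=lambda: {"R+": 0.48, "R-": 0.82})
    #: non-self neighbour perceived-competition discount (dimensionless)
    kappa: float = 0.60
    #: weight of the focal genotype's own area in the plastic exponent
    focal_weight: float = 0.4
    theta_cap: float = 0.95
    area_scale: dict = field(default_factory=lambda: {"R+": 1.0, "R-": 1.15})
    block_effects: tuple = (0.97, 1.00, 1.03)
    date_effects: tuple = (0.94, 0.98, 1.02, 1.06)
    sigma_res: float = 0.10
    sigma_rho: float = 0.05
    sigma_tube_area: float = 0.05
    sigma_tube_length: float = 0.05
    #: cm of root length per mm^2 of projected area (1 / effective diameter)
    length_per_area: float = 0.25
    target_pure_totals: dict = field(
        default_factory=lambda: {"R+": 2364.71, "R-": 1947.35}
    )
    leaf_base: dict = field(default_factory=lambda: {"R+": 4.5, "R-": 4.0})
    tiller_base: dict = field(default_factory=lambda: {"R+": 2.5, "R-": 1.8})
    leaf_n_base: dict = field(default_factory=lambda: {"R+": 2.95, "R-": 3.32})
    leaf_slope: float = 1.2
    tiller_slope: float = 1.0
    leaf_n_slope: float = -0.1
    sigma_plant_counts: float = 0.30
    sigma_plant_leaf_n: float = 0.05

    def __post_init__(self) -> None:
        for name in ("theta", "delta"):
            for k, v in getattr(self, name).items():
                if v < 0:
                    raise ValueError(f"{name}[{k}] must be >= 0, got {v}")
        if self.gamma <= 0 or self.kappa <= 0 or self.sigma_res < 0:
            raise ValueError("gamma and kappa must be positive, sigma_res >= 0")
        for k, v in self.rho.items():
            if v <= 0:
                raise ValueError(f"rho[{k}] must be > 0, got {v}")

    def to_dict(self) -> dict:
        return asdict(self)


def make_genotypes(
    n: int,
    seed: int | np.random.Generator = 0,
    mean_area: float = 4000.0,
    sigma_log_area: float = 0.30,
    clip_sd: float = 2.0,
    sigma_leaf: float = 0.35,
    sigma_tiller: float = 0.30,
    sigma_leaf_n: float = 0.09,
    sigma_length_ratio: float = 0.18,
) -> pd.DataFrame:
    """Draw a genotype panel.

    Intrinsic areas are lognormal around ``mean_area`` and clipped at
    ``clip_sd`` log-SDs: a varietal panel spans a limited range, and the
    clip keeps a single extreme genotype from dominating every mixture it
    enters.  Alongside the area, each genotype gets latent trait deviations
    (leaves, tillers, leaf N, length:area ratio) that are independent of
    area, so above-ground traits are only loosely coupled to below-ground
    competitiveness.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    z = rng.normal(0.0, 1.0, n)
    area = mean_area * np.exp(np.clip(z * sigma_log_area, -clip_sd * sigma_log_area,
                                      clip_sd * sigma_log_area))
    return pd.DataFrame(
        {
            "genotype_id": [f"G{i + 1:02d}" for i in range(n)],
            "intrinsic_root_area": area,
            "baseline_vigor": np.clip(z, -clip_sd, clip_sd),
            "d_leaves": rng.normal(0.0, sigma_leaf, n),
            "d_tillers": rng.normal(0.0, sigma_tiller, n),
            "d_leaf_n": rng.normal(0.0, sigma_leaf_n, n),
            "d_length": rng.normal(0.0, sigma_length_ratio, n),
        }
    )


def plastic_root_area(a_focal, a_neighbor, theta):
    """Realized per-plant root area under a plastic response to the neighbour.

    Geometric interpolation ``a_focal**(1-theta) * a_neighbor**theta``:
    scale-free, positivity-preserving, and the identity when the neighbour
    matches the focal plant (pure stands) or when theta = 0.
    """
    a_focal = np.asarray(a_focal, dtype=float)
    a_neighbor = np.asarray(a_neighbor, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if np.any(a_focal <= 0) or np.any(a_neighbor <= 0):
        raise ValueError("root areas must be positive")
    if np.any(theta < 0) or np.any(theta >= 1):
        raise ValueError("theta must satisfy 0 <= theta < 1")
    out = a_focal ** (1.0 - theta) * a_neighbor ** theta
    return float(out) if out.ndim == 0 else out


def calibrate_biomass_scale(
    genotypes: pd.DataFrame, params: SimulationParams, treatments=("R+", "R-")
) -> dict:
    """Biomass scale m_k so expected pure-stand tube totals match targets.

    Inverts E[tube total] = 6 * m_k * mean_g[a_g^gamma / (1 + delta_k a_g)]
    over the panel (block/date effects and the residual lognormal are
    mean-one by construction).
    """
    panel = genotypes[genotypes["genotype_id"] != CONTROL_GENOTYPE]
    m = {}
    for k in treatments:
        a = panel["intrinsic_root_area"].to_numpy() * params.area_scale[k]
        per_plant = np.mean(a ** params.gamma / (1.0 + params.delta[k] * a))
        m[k] = params.target_pure_totals[k] / (PLANTS_PER_POT * per_plant)
    return m


def simulate_plant_biomass(
    realized_areas,
    params: SimulationParams,
    treatment: str,
    block: int,
    date: int,
    rng: np.random.Generator,
    m: float | None = None,
    genotype_latents: pd.DataFrame | None = None,
):
    """Simulate the six plants of one tube given their realized root areas.

    Returns a DataFrame with per-plant total/shoot/root biomass and the
    trait covariates (leaf and tiller counts, leaf N), generated as monotone
    noisy functions of shoot biomass with treatment-level shifts (resource
    limitation lowers the counts and raises leaf N).
    """
    a = np.asarray(realized_areas, dtype=float)
    if a.shape != (PLANTS_PER_POT,):
        raise ValueError(f"expected {PLANTS_PER_POT} realized areas, got {a.shape}")
    if np.any(a <= 0):
        raise ValueError("realized areas must be positive")
    if m is None:
        if params.m is None:
            raise ValueError("no biomass scale: pass m or set params.m")
        m = params.m[treatment]
    delta = params.delta[treatment]
    rho_k = params.rho[treatment]
    a_bar = a.mean()
    block_eff = params.block_effects[(block - 1) % len(params.block_effects)]
    date_eff = params.date_effects[(date - 1) % len(params.date_effects)]
    s = params.sigma_res
    noise = np.exp(rng.normal(-0.5 * s * s, s, PLANTS_PER_POT)) if s > 0 else 1.0
    total = m * a ** params.gamma / (1.0 + delta * a_bar) * block_eff * date_eff * noise

    rho = rho_k * np.exp(rng.normal(0.0, params.sigma_rho, PLANTS_PER_POT))
    root = total * rho / (1.0 + rho)
    shoot = total - root

    # expected per-plant shoot at the panel average, used to centre the
    # covariate link on the treatment scale
    shoot_ref = params.target_pure_totals[treatment] / PLANTS_PER_POT / (1.0 + rho_k)
    z = np.log(shoot / shoot_ref)
    if genotype_latents is not None:
        d_leaves = genotype_latents["d_leaves"].to_numpy()
        d_tillers = genotype_latents["d_tillers"].to_numpy()
        d_leaf_n = genotype_latents["d_leaf_n"].to_numpy()
    else:
        d_leaves = d_tillers = d_leaf_n = np.zeros(PLANTS_PER_POT)
    eps = params.sigma_plant_counts
    n_leaves = np.maximum(
        1,
        np.rint(params.leaf_base[treatment] + params.leaf_slope * z + d_leaves
                + rng.normal(0, eps, PLANTS_PER_POT)),
    ).astype(int)
    n_tillers = np.maximum(
        1,
        np.rint(params.tiller_base[treatment] + params.tiller_slope * z + d_tillers
                + rng.normal(0, eps, PLANTS_PER_POT)),
    ).astype(int)
    leaf_n = np.maximum(
        0.5,
        params.leaf_n_base[treatment] + params.leaf_n_slope * z + d_leaf_n
        + rng.normal(0, params.sigma_plant_leaf_n, PLANTS_PER_POT),
    )
    return pd.DataFrame(
        {
            "position": np.arange(1, PLANTS_PER_POT + 1),
            "shoot_biomass": shoot,
            "root_biomass": root,
            "total_biomass": total,
            "n_leaves": n_leaves,
            "n_tillers": n_tillers,
            "leaf_n": leaf_n,
        }
    )


def realized_tube_areas(
    composition: list[str],
    areas: dict,
    params: SimulationParams,
    treatment: str,
    panel_mean_area: float,
) -> np.ndarray:
    """Realized per-plant areas for one tube (before treatment area scaling)."""
    distinct = sorted(set(composition))
    theta_k = params.theta[treatment]
    if len(distinct) == 1 or theta_k == 0.0:
        base = np.array([areas[g] for g in composition])
    elif len(distinct) == 2:
        g1, g2 = distinct
        a1, a2 = areas[g1], areas[g2]
        pair_mean = 0.5 * (a1 + a2)
        w = params.focal_weight
        base = np.empty(len(composition))
        for i, g in enumerate(composition):
            a_f = areas[g]
            a_n = a2 if g == g1 else a1
            th = min(theta_k * (w * a_f + (1 - w) * pair_mean) / panel_mean_area,
                     params.theta_cap)
            base[i] = plastic_root_area(a_f, params.kappa * a_n, th)
    else:
        raise ValueError(f"tube composition has {len(distinct)} genotypes; max 2")
    return base * params.area_scale[treatment]


def simulate_experiment(
    genotypes: pd.DataFrame,
    design: pd.DataFrame,
    params: SimulationParams | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate per-plant and per-tube observations for a design.

    Control pots are carried in the design but receive no observations (they
    only audit greenhouse heterogeneity and are excluded from every
    downstream statistic).

    Returns ``(plants, tubes)``: one plant record per position per
    non-control pot, one root-image record (root length cm, projected root
    area mm^2) per non-control pot.
    """
    params = params or SimulationParams()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pos_cols = [c for c in design.columns if c.startswith("pos")]

    known = set(genotypes["genotype_id"])
    panel = genotypes.set_index("genotype_id")
    areas = panel["intrinsic_root_area"].to_dict()
    non_ctrl = design[~design["is_control"]]
    used = set(non_ctrl[pos_cols].to_numpy().ravel()) if len(non_ctrl) else set()
    if not used <= known:
        missing = sorted(used - known)
        raise ValueError(f"design references unknown genotypes: {missing}")
    panel_mean_area = float(
        genotypes.loc[genotypes["genotype_id"] != CONTROL_GENOTYPE,
                      "intrinsic_root_area"].mean()
    ) if len(genotypes) else np.nan

    m = params.m or calibrate_biomass_scale(
        genotypes, params, treatments=tuple(dict.fromkeys(design["treatment"]))
    ) if len(design) else {}

    plant_frames, tube_rows = [], []
    for _, row in non_ctrl.iterrows():
        comp = [row[c] for c in pos_cols]
        treatment = row["treatment"]
        a = realized_tube_areas(comp, areas, params, treatment, panel_mean_area)
        latents = panel.loc[comp, ["d_leaves", "d_tillers", "d_leaf_n"]].reset_index()
        plants = simulate_plant_biomass(
            a, params, treatment, int(row["block"]), int(row["harvest_date"]),
            rng, m=m[treatment], genotype_latents=latents,
        )
        plants.insert(0, "tube_id", row["tube_id"])
        plants.insert(2, "genotype_id", comp)
        plant_frames.append(plants)

        sa = params.sigma_tube_area
        area_obs = a.sum() * (
            np.exp(rng.normal(-0.5 * sa * sa, sa)) if sa > 0 else 1.0
        )
        d_len = panel.loc[sorted(set(comp)), "d_length"].mean()
        sl = params.sigma_tube_length
        length_obs = area_obs * params.length_per_area * np.exp(
            d_len + (rng.normal(-0.5 * sl * sl, sl) if sl > 0 else 0.0)
        )
        tube_rows.append(
            {"tube_id": row["tube_id"], "root_length": length_obs, "root_area": area_obs}
        )

    plants = (
        pd.concat(plant_frames, ignore_index=True)[PLANT_COLUMNS]
        if plant_frames
        else pd.DataFrame(columns=PLANT_COLUMNS)
    )
    tubes = pd.DataFrame(tube_rows, columns=TUBE_COLUMNS)
    return plants, tubes


def arms_race_scenario(seed: int = 0, n_genotypes: int = 36):
    """The default study conditions: 36 genotypes, 54 mixtures, 3 blocks,
    2 treatments, 4 harvest dates, 6 controls per block per treatment."""
    rng = np.random.default_rng(seed)
    genotypes = make_genotypes(n_genotypes, rng)
    ctrl = pd.DataFrame(
        {
            "genotype_id": [CONTROL_GENOTYPE],
            "intrinsic_root_area": [float(genotypes["intrinsic_root_area"].mean())],
            "baseline_vigor": [0.0], "d_leaves": [0.0], "d_tillers": [0.0],
            "d_leaf_n": [0.0], "d_length": [0.0],
        }
    )
    genotypes = pd.concat([genotypes, ctrl], ignore_index=True)
    design = generate_design(
        [g for g in genotypes["genotype_id"] if g != CONTROL_GENOTYPE],
        mixtures_per_genotype=3, n_blocks=3, treatments=("R+", "R-"),
        n_dates=4, controls_per_block_per_treatment=6, seed=rng,
    )
    return genotypes, design, SimulationParams(), rng


def null_scenario(seed: int = 0, n_genotypes: int = 36, sigma_res: float = 0.10):
    """No plasticity, no shared-resource interaction: theta = delta = 0 in
    both treatments and unit block/date effects, so mixtures behave exactly
    like half a pure stand up to residual noise."""
    genotypes, design, params, rng = arms_race_scenario(seed, n_genotypes)
    params = replace(
        params,
        theta={"R+": 0.0, "R-": 0.0},
        delta={"R+": 0.0, "R-": 0.0},
        block_effects=(1.0, 1.0, 1.0),
        date_effects=(1.0, 1.0, 1.0, 1.0),
        sigma_res=sigma_res,
    )
    return genotypes, design, params, rng


SCENARIOS = {"arms_race": arms_race_scenario, "null": null_scenario}
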