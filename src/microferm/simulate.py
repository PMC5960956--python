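"""Synthetic microcosm measurements and amplicon count tables.

Generators invert the speciation model so that the full pipeline
(speciate -> net -> recovery) recovers configured ground truth exactly
at zero noise, and emulate paired treatment/control amplicon designs
with designated responder taxa on a stable background community.

All randomness flows from one seed.  Stream order for the microcosm
generator: arm (treatment before control), then replicate, then time
point, then analyte, each in sorted order.  The count generator draws
one multinomial per (arm, period) sample in grid order, treatment arm
first, after an optional Dirichlet perturbation per sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .balance import SubstrateSpec
from .chem import DEFAULT_REGISTRY, CompoundSpec
from .constants import DEFAULT_PRESSURE_KPA, DEFAULT_TEMPERATURE_K
from .speciation import (
    DEFAULT_CONSTANTS,
    GasObservation,
    PhysicalConstants,
    VialGeometry,
    bicarbonate_amount,
    dissolved_gas_amount,
    headspace_amount,
)

GASES = {"H2", "CO2"}

LYSATE_GRID = (0.0, 6.0, 12.0, 20.0, 30.0)
BIOPOLYMER_GRID = (0.0, 10.0, 20.0, 30.0)


class ScenarioError(ValueError):
    pass


@dataclass
class FermentationScenario:
    """Ground truth for one treatment/control microcosm experiment."""

    substrate: SubstrateSpec
    yields_carbon: dict[str, float]  # compound -> carbon-basis yield at end
    h2_electron_yield: float = 0.0
    transient_peaks: dict[str, float] = field(default_factory=dict)  # carbon basis
    control_baseline: dict[str, float] = field(default_factory=dict)  # umol/g_FW at end
    lag_h: float = 6.0
    rate_per_h: float = 0.35
    noise_rel_sd: float = 0.0
    replicates: int = 3
    grid_h: tuple[float, ...] = LYSATE_GRID
    geometry: VialGeometry = field(default_factory=VialGeometry)
    constants: PhysicalConstants = field(default_factory=lambda: DEFAULT_CONSTANTS)
    ph: float = 7.0
    pressure_kpa: float = DEFAULT_PRESSURE_KPA
    temperature_k: float = DEFAULT_TEMPERATURE_K
    registry: dict[str, CompoundSpec] = field(default_factory=lambda: DEFAULT_REGISTRY)
    seed: int = 0

    def __post_init__(self) -> None:
        grid = tuple(float(t) for t in self.grid_h)
        if len(grid) < 3 or any(b <= a for a, b in zip(grid, grid[1:])):
            raise ScenarioError("grid must be >= 3 strictly increasing time points")
        self.grid_h = grid
        for name in (*self.yields_carbon, *self.transient_peaks, *self.control_baseline):
            if name not in self.registry:
                raise ScenarioError(f"compound {name!r} not in registry")
        for name, f in self.yields_carbon.items():
            if not 0.0 <= f <= 1.0:
                raise ScenarioError(f"yield for {name} out of [0,1]")
            if self.registry[name].carbon_atoms == 0:
                raise ScenarioError(
                    f"{name} is carbon-free; use h2_electron_yield for H2"
                )
        if not 0.0 <= self.h2_electron_yield <= 1.0:
            raise ScenarioError("h2_electron_yield out of [0,1]")
        c_sum = sum(self.yields_carbon.values())
        if c_sum > 1.0 + 1e-12:
            raise ScenarioError(f"carbon yields sum to {c_sum} > 1")
        if self.electron_yield_sum() > 1.0 + 1e-12:
            raise ScenarioError("implied electron yields sum to > 1")

    def electron_yield_of(self, name: str) -> float:
        spec = self.registry[name]
        if spec.carbon_atoms == 0:
            return self.h2_electron_yield if name == "H2" else 0.0
        return (
            self.yields_carbon.get(name, 0.0)
            * spec.electrons_per_carbon
            / self.substrate.n_r_c
        )

    def electron_yield_sum(self) -> float:
        total = sum(self.electron_yield_of(n) for n in self.yields_carbon)
        return total + self.h2_electron_yield

    def end_net_umol_per_gfw(self, name: str) -> float:
        """True treatment-minus-control amount at the final time point."""
        fw = self.geometry.fresh_weight_g
        spec = self.registry[name]
        if name == "H2":
            return self.h2_electron_yield * self.substrate.n_r_umol / 2.0 / fw
        f = self.yields_carbon.get(name, 0.0)
        return f * self.substrate.n_c_umol / spec.carbon_atoms / fw


def _logistic(t: np.ndarray, lag: float, rate: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-rate * (t - lag)))


def accumulation_shape(grid: np.ndarray, lag: float, rate: float) -> np.ndarray:
    """Monotone logistic time course, pinned exactly to 0 at t0 and 1 at the end."""
    raw = _logistic(grid, lag, rate)
    return (raw - raw[0]) / (raw[-1] - raw[0])


def transient_shape(grid: np.ndarray, lag: float, rate: float) -> np.ndarray:
    """Rise-then-fall course, exactly 0 at both ends, max exactly 1 on the grid."""
    span = grid[-1] - grid[0]
    rise = _logistic(grid, lag, rate)
    fall = _logistic(grid, grid[0] + 0.6 * span, rate)
    raw = rise - fall
    raw = raw - raw[0] - (grid - grid[0]) / span * (raw[-1] - raw[0])
    peak = raw.max()
    if peak <= 0:
        raise ScenarioError("degenerate transient shape; adjust lag/rate")
    return raw / peak


def _gas_amount_per_mixing_ratio(
    analyte: str,
    geom: VialGeometry,
    k: PhysicalConstants,
    ph: float,
    pressure_kpa: float,
    temperature_k: float,
) -> float:
    """Total umol of gas per unit mixing ratio (the linear inversion slope)."""
    probe = GasObservation(
        time_h=0.0,
        analyte=analyte,
        mixing_ratio=1.0,
        pressure_kpa=pressure_kpa,
        temperature_k=temperature_k,
    )
    total = headspace_amount(probe, geom) + dissolved_gas_amount(probe, geom, k)
    if analyte == "CO2":
        total += bicarbonate_amount(dissolved_gas_amount(probe, geom, k), ph, k)
    return total


def simulate_microcosm(
    scenario: FermentationScenario, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a measurement table plus its ground truth.

    Returns ``(measurements, truth)``: measurements in the speciation
    input schema for both arms; truth with one row per compound giving
    the configured end net amount and yields.
    """
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    geom = scenario.geometry
    grid = np.asarray(scenario.grid_h)
    rise = accumulation_shape(grid, scenario.lag_h, scenario.rate_per_h)
    bump = (
        transient_shape(grid, scenario.lag_h, scenario.rate_per_h)
        if scenario.transient_peaks
        else None
    )

    analytes = sorted(
        {
            *scenario.yields_carbon,
            *scenario.transient_peaks,
            *scenario.control_baseline,
            *({"H2"} if scenario.h2_electron_yield > 0 else set()),
        }
    )

    # true per-arm amounts, umol/g_FW, per time point
    fw = geom.fresh_weight_g
    profiles: dict[tuple[str, str], np.ndarray] = {}
    for name in analytes:
        base = scenario.control_baseline.get(name, 0.0) * rise
        net = scenario.end_net_umol_per_gfw(name) * rise
        if name in scenario.transient_peaks:
            spec = scenario.registry[name]
            peak = (
                scenario.transient_peaks[name]
                * scenario.substrate.n_c_umol
                / spec.carbon_atoms
                / fw
            )
            net = net + peak * bump
        profiles[("control", name)] = base
        profiles[("treatment", name)] = base + net

    rows = []
    for arm in ("treatment", "control"):
        for rep in range(1, scenario.replicates + 1):
            for i, t in enumerate(grid):
                for name in analytes:
                    amount_gfw = profiles[(arm, name)][i]
                    amount_total = amount_gfw * fw
                    if name in GASES:
                        slope = _gas_amount_per_mixing_ratio(
                            name,
                            geom,
                            scenario.constants,
                            scenario.ph,
                            scenario.pressure_kpa,
                            scenario.temperature_k,
                        )
                        value = amount_total / slope
                        if value > 1.0:
                            raise ScenarioError(
                                f"{name} mixing ratio {value:.3f} > 1; lower yields "
                                "or raise pressure"
                            )
                        phase, unit = "headspace", "mol_fraction"
                    else:
                        value = amount_total / geom.liquid_ml
                        phase, unit = "liquid", "mM"
                    if scenario.noise_rel_sd > 0:
                        value = max(
                            0.0, value * (1.0 + scenario.noise_rel_sd * rng.standard_normal())
                        )
                    rows.append(
                        {
                            "microcosm_id": f"{arm}_r{rep}",
                            "treatment": arm,
                            "replicate": f"r{rep}",
                            "time_h": t,
                            "analyte": name,
                            "phase": phase,
                            "value": value,
                            "unit": unit,
                            "pressure_kPa": scenario.pressure_kpa,
                            "temperature_K": scenario.temperature_k,
                            "pH": scenario.ph,
                        }
                    )

    truth_rows = [
        {
            "analyte": name,
            "end_net_umol_per_gfw": scenario.end_net_umol_per_gfw(name),
            "carbon_yield": scenario.yields_carbon.get(name, 0.0),
            "electron_yield": scenario.electron_yield_of(name),
            "transient": name in scenario.transient_peaks,
        }
        for name in analytes
    ]
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


@dataclass
class CommunityScenario:
    """Paired treatment/control amplicon design with known responders."""

    background: pd.Series  # taxon -> proportion, sums to 1
    taxonomy: pd.DataFrame  # indexed by taxon: phylum, family, phylotype
    responders: dict[str, dict[float, float]]  # taxon -> {period: increase (proportion)}
    periods: tuple[float, ...] = BIOPOLYMER_GRID
    depth: int = 50_000
    dispersion: float | None = None  # Dirichlet concentration; None disables
    seed: int = 0

    def __post_init__(self) -> None:
        p = self.background
        if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ScenarioError("background proportions must be >= 0 and sum to 1")
        if self.depth <= 0:
            raise ScenarioError("depth must be positive")
        unknown = set(self.responders) - set(p.index)
        if unknown:
            raise ScenarioError(f"responders not in background: {sorted(unknown)}")
        missing_tax = p.index.difference(self.taxonomy.index)
        if len(missing_tax):
            raise ScenarioError(f"taxa missing from taxonomy: {list(missing_tax)[:5]}")

    def arm_proportions(self, arm: str, period: float) -> pd.Series:
        """Exact per-taxon proportions for one arm at one period."""
        p = self.background.astype(float).copy()
        if arm == "control" or float(period) == 0.0:
            return p
        increases = {
            tax: per.get(period, per.get(float(period), 0.0))
            for tax, per in self.responders.items()
        }
        resp = [t for t, inc in increases.items() if inc > 0]
        if not resp:
            return p
        bg_resp = p.loc[resp].sum()
        inc_sum = sum(increases[t] for t in resp)
        scale = (1.0 - bg_resp - inc_sum) / (1.0 - bg_resp)
        if scale < 0:
            raise ScenarioError("responder increases exceed available background mass")
        out = p * scale
        for t in resp:
            out.loc[t] = p.loc[t] + increases[t]
        return out

    def true_max_increase_pp(self, taxon: str) -> float:
        """Largest treatment-minus-control difference across periods, in pp."""
        best = 0.0
        for period in self.periods:
            if float(period) == 0.0:
                continue
            diff = (
                self.arm_proportions("treatment", period).loc[taxon]
                - self.arm_proportions("control", period).loc[taxon]
            )
            best = max(best, diff * 100.0)
        return best


def expected_abundance_tables(
    scenario: CommunityScenario,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Noise-free percent-abundance tables (taxa x periods) for both arms."""
    cols = {}
    for period in scenario.periods:
        cols[period] = scenario.arm_proportions("treatment", period) * 100.0
    treat = pd.DataFrame(cols)
    cols = {}
    for period in scenario.periods:
        cols[period] = scenario.arm_proportions("control", period) * 100.0
    ctrl = pd.DataFrame(cols)
    return treat, ctrl


def simulate_counts(
    scenario: CommunityScenario, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw count tables for both arms with known truth labels.

    Returns ``(counts, metadata, truth)``.  Counts: taxa x samples; one
    pooled sample per (arm, period).  Metadata indexed by sample id with
    arm and period.  Truth: per-taxon true maximum increase (pp).
    """
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    samples = {}
    meta = []
    for arm in ("treatment", "control"):
        for period in scenario.periods:
            p = scenario.arm_proportions(arm, period).to_numpy()
            if scenario.dispersion is not None:
                positive = p > 0
                alpha = p[positive] * scenario.dispersion
                drawn = rng.dirichlet(alpha)
                p = p.copy()
                p[positive] = drawn
            counts = rng.multinomial(scenario.depth, p)
            sample_id = f"{arm}_{period:g}h"
            samples[sample_id] = counts
            meta.append({"sample": sample_id, "arm": arm, "time_h": period})
    counts = pd.DataFrame(samples, index=scenario.background.index)
    metadata = pd.DataFrame(meta).set_index("sample")
    truth = pd.DataFrame(
        {
            "true_max_increase_pp": {
                t: scenario.true_max_increase_pp(t) for t in scenario.background.index
            }
        }
    )
    truth.index.name = scenario.background.index.name
    return counts, metadata, truth


def responder_benchmark(
    n_scenarios: int = 200,
    n_taxa: int = 30,
    n_responders: int = 3,
    effect_pp: float = 4.0,
    threshold_pp: float = 2.0,
    depth: int = 50_000,
    seed: int = 0,
) -> dict[str, float]:
    """Operating characteristics of the responder screen on simulated data.

    Each scenario draws a random background community, elevates
    ``n_responders`` taxa by ``effect_pp`` percentage points in at least
    one period, simulates paired count tables (no overdispersion), runs
    the screen at ``threshold_pp``, and tallies detections against
    truth.  Returns sensitivity and specificity.
    """
    from .community import relative_abundances, responsive_taxa

    master = np.random.default_rng(seed)
    tp = fn = tn = fp = 0
    for _ in range(n_scenarios):
        sub_seed = int(master.integers(0, 2**31 - 1))
        rng = np.random.default_rng(sub_seed)
        taxa = [f"pt{i:03d}" for i in range(n_taxa)]
        background = pd.Series(rng.dirichlet(np.full(n_taxa, 5.0)), index=taxa)
        # keep responders away from dominating taxa so increases stay feasible
        order = background.sort_values().index
        responders = list(order[:n_responders])
        periods = (0.0, 10.0, 20.0, 30.0)
        active = {
            t: {float(rng.choice(periods[1:])): effect_pp / 100.0} for t in responders
        }
        taxonomy = pd.DataFrame(
            {"phylum": "p", "family": [f"f{i}" for i in range(n_taxa)], "phylotype": taxa},
            index=taxa,
        )
        scen = CommunityScenario(
            background=background,
            taxonomy=taxonomy,
            responders=active,
            periods=periods,
            depth=depth,
            dispersion=None,
            seed=sub_seed,
        )
        counts, metadata, truth = simulate_counts(scen)
        rel = relative_abundances(counts, remove_singletons=False) * 100.0
        t_cols = metadata.index[metadata["arm"] == "treatment"]
        c_cols = metadata.index[metadata["arm"] == "control"]
        treat = rel[t_cols]
        treat.columns = metadata.loc[t_cols, "time_h"]
        ctrl = rel[c_cols]
        ctrl.columns = metadata.loc[c_cols, "time_h"]
        report = responsive_taxa(treat, ctrl, threshold_pp=threshold_pp)
        for taxon in taxa:
            truly = truth.loc[taxon, "true_max_increase_pp"] >= threshold_pp
            called = bool(report.loc[taxon, "responsive"])
            if truly and called:
                tp += 1
            elif truly:
                fn += 1
            elif called:
                fp += 1
            else:
                tn += 1
    return {
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
        "n_true": tp + fn,
        "n_null": tn + fp,
    }
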