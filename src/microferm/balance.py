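"""Net product profiles and carbon / reducing-equivalent recovery accounting.

Net amounts are treatment-arm replicate means minus control-arm
replicate means on a shared sampling grid.  Recoveries express, per
fermentation product, the fraction of supplemented substrate carbon
(and electrons) found in that product at the end of the incubation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem import DEFAULT_REGISTRY, CompoundSpec
from .presets import SubstratePreset

EXCLUDED = "—"  # sentinel for products with no net increase


class BalanceError(ValueError):
    pass


@dataclass
class TreatmentSeries:
    """Per-replicate analyte time series for one treatment arm."""

    treatment: str
    replicate: str
    times_h: np.ndarray
    amounts: dict[str, np.ndarray]  # analyte -> umol/g_FW per time point

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        if self.times_h.ndim != 1 or np.any(np.diff(self.times_h) <= 0):
            raise BalanceError("time points must be strictly increasing")
        for analyte, series in self.amounts.items():
            arr = np.asarray(series, dtype=float)
            if arr.shape != self.times_h.shape:
                raise BalanceError(f"{analyte}: series length != grid length")
            if np.any(arr < 0):
                raise BalanceError(f"{analyte}: amounts must be >= 0")
            self.amounts[analyte] = arr

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> list["TreatmentSeries"]:
        """Build series from a tidy speciation output table."""
        out = []
        for (trt, rep), grp in df.groupby(["treatment", "replicate"], sort=True):
            wide = grp.pivot_table(
                index="time_h", columns="analyte", values="umol_per_gfw", sort=True
            )
            out.append(
                cls(
                    treatment=str(trt),
                    replicate=str(rep),
                    times_h=wide.index.to_numpy(),
                    amounts={a: wide[a].to_numpy() for a in wide.columns},
                )
            )
        return out


@dataclass
class NetProfile:
    """Treatment-minus-control time series for one analyte."""

    analyte: str
    times_h: np.ndarray
    net: np.ndarray  # may be negative
    transient_tol: float = 0.5

    @property
    def end_net(self) -> float:
        return float(self.net[-1])

    @property
    def transient(self) -> bool:
        """True when the product peaks at an interior point but shows no
        net increase at the end of the incubation."""
        if len(self.net) < 3:
            return False
        interior = self.net[1:-1]
        return bool(interior.max() > self.transient_tol and self.end_net <= self.transient_tol)


def _mean_series(arm: list[TreatmentSeries]) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    if not arm:
        raise BalanceError("empty replicate set")
    grid = arm[0].times_h
    for s in arm[1:]:
        if not np.array_equal(s.times_h, grid):
            raise BalanceError(
                f"replicate {s.replicate!r} sampling grid differs; no interpolation is done"
            )
    analytes = set(arm[0].amounts)
    for s in arm[1:]:
        if set(s.amounts) != analytes:
            raise BalanceError("replicates disagree on the analyte panel")
    means = {a: np.mean([s.amounts[a] for s in arm], axis=0) for a in analytes}
    return grid, means


def net_products(
    treatment: list[TreatmentSeries],
    control: list[TreatmentSeries],
    transient_tol: float = 0.5,
) -> dict[str, NetProfile]:
    """Replicate-mean treatment minus replicate-mean control per analyte.

    Both arms must share one sampling grid and one analyte panel;
    negative net values are retained in the series.
    """
    t_grid, t_mean = _mean_series(treatment)
    c_grid, c_mean = _mean_series(control)
    if not np.array_equal(t_grid, c_grid):
        raise BalanceError("treatment and control sampling grids differ")
    missing = set(t_mean) ^ set(c_mean)
    if missing:
        raise BalanceError(f"analytes present in only one arm: {sorted(missing)}")
    return {
        a: NetProfile(a, t_grid, t_mean[a] - c_mean[a], transient_tol=transient_tol)
        for a in sorted(t_mean)
    }


def substrate_carbon_umol(
    molar_mass_per_c: float,
    volume_ml: float = 1.0,
    dry_weight_fraction: float | None = None,
    mass_concentration_mg_ml: float | None = None,
    mass_g: float | None = None,
) -> float:
    """Micromoles of carbon delivered by a substrate addition.

    Exactly one of ``dry_weight_fraction`` (g dry mass per g, assuming
    1 g/ml for the added liquid), ``mass_concentration_mg_ml``, or a
    direct ``mass_g`` must be given.
    """
    if molar_mass_per_c <= 0:
        raise BalanceError("per-carbon molar mass must be positive")
    given = [dry_weight_fraction, mass_concentration_mg_ml, mass_g]
    if sum(x is not None for x in given) != 1:
        raise BalanceError(
            "specify exactly one of dry_weight_fraction, "
            "mass_concentration_mg_ml, mass_g"
        )
    if dry_weight_fraction is not None:
        grams = volume_ml * dry_weight_fraction
    elif mass_concentration_mg_ml is not None:
        grams = volume_ml * mass_concentration_mg_ml / 1000.0
    else:
        grams = float(mass_g)  # type: ignore[arg-type]
    return grams / molar_mass_per_c * 1e6


@dataclass(frozen=True)
class SubstrateSpec:
    """Carbon and electron inventory of the supplemented substrate."""

    label: str
    n_c_umol: float
    n_r_c: float
    provenance: str = "computed"  # computed | printed-override
    kind: str = "generic"
    carbon_per_unit: float | None = None

    def __post_init__(self) -> None:
        if self.n_c_umol <= 0:
            raise BalanceError("substrate carbon must be positive")
        if self.n_r_c <= 0:
            raise BalanceError("substrate degree of reduction must be positive")

    @property
    def n_r_umol(self) -> float:
        """Total reducing equivalents supplemented: n_c x n_r_C."""
        return self.n_c_umol * self.n_r_c

    @classmethod
    def from_preset(cls, preset: SubstratePreset, n_c_umol: float) -> "SubstrateSpec":
        nrc, provenance = preset.n_r_c()
        return cls(
            label=preset.label,
            n_c_umol=n_c_umol,
            n_r_c=nrc,
            provenance=provenance,
            kind=preset.kind,
            carbon_per_unit=preset.carbon_per_unit,
        )


@dataclass(frozen=True)
class RecoveryEntry:
    analyte: str
    carbon_pct: float | None  # None: not applicable (carbon-free product)
    electron_pct: float | None  # None: not applicable (electron-free product)
    included: bool = True


@dataclass
class RecoveryTable:
    """Per-compound and total recovery percentages for one treatment."""

    substrate: SubstrateSpec
    entries: list[RecoveryEntry] = field(default_factory=list)

    @property
    def total_carbon_pct(self) -> float:
        return sum(
            e.carbon_pct for e in self.entries if e.included and e.carbon_pct is not None
        )

    @property
    def total_electron_pct(self) -> float:
        return sum(
            e.electron_pct for e in self.entries if e.included and e.electron_pct is not None
        )

    def to_frame(self, decimals: int = 1) -> pd.DataFrame:
        """Render with the excluded/not-applicable sentinels, plus a Total row."""
        rows = []
        for e in self.entries:
            if not e.included:
                rows.append({"product": e.analyte, "carbon_pct": EXCLUDED, "electron_pct": EXCLUDED})
            else:
                rows.append(
                    {
                        "product": e.analyte,
                        "carbon_pct": "NA" if e.carbon_pct is None else round(e.carbon_pct, decimals),
                        "electron_pct": "NA"
                        if e.electron_pct is None
                        else round(e.electron_pct, decimals),
                    }
                )
        rows.append(
            {
                "product": "Total",
                "carbon_pct": round(self.total_carbon_pct, decimals),
                "electron_pct": round(self.total_electron_pct, decimals),
            }
        )
        return pd.DataFrame(rows)

    @classmethod
    def from_printed(
        cls,
        substrate: SubstrateSpec,
        carbon_pct: dict[str, float],
        electron_pct: dict[str, float],
    ) -> "RecoveryTable":
        """Populate a table directly from per-compound percentages.

        Useful for re-deriving totals and cross-checking published
        balance tables; products absent from a column are marked not
        applicable there.
        """
        entries = []
        for name in dict.fromkeys([*carbon_pct, *electron_pct]):
            entries.append(
                RecoveryEntry(
                    analyte=name,
                    carbon_pct=carbon_pct.get(name),
                    electron_pct=electron_pct.get(name),
                )
            )
        return cls(substrate=substrate, entries=entries)


def electron_from_carbon_pct(
    carbon_pct: float, compound: CompoundSpec, n_r_c: float
) -> float:
    """Convert a carbon recovery to its electron recovery.

    e% = C% x (gamma_X / c_X) / n_r_C — both recoveries share the same
    net amount, so the ratio is pure stoichiometry.
    """
    if compound.carbon_atoms == 0:
        raise BalanceError(f"{compound.name} has no carbon; identity undefined")
    return carbon_pct * compound.electrons_per_carbon / n_r_c


def recovery_table(
    nets: dict[str, NetProfile],
    substrate: SubstrateSpec,
    registry: dict[str, CompoundSpec] | None = None,
    at: float | None = None,
    exclusion_tol: float = 0.5,
) -> RecoveryTable:
    """Build the recovery table at a sampling time (default: final point).

    Products whose net amount at ``at`` is at or below ``exclusion_tol``
    are excluded (negative nets are never clipped into the totals).
    Carbon-free products (H2) contribute only to the electron column;
    electron-free products (CO2) only to the carbon column.
    """
    registry = DEFAULT_REGISTRY if registry is None else registry
    entries = []
    for analyte, profile in sorted(nets.items()):
        if analyte not in registry:
            raise BalanceError(f"no compound registry entry for {analyte!r}")
        spec = registry[analyte]
        if at is None:
            net = profile.end_net
        else:
            idx = np.flatnonzero(np.isclose(profile.times_h, at))
            if idx.size == 0:
                raise BalanceError(
                    f"time {at} h is not on the sampling grid {profile.times_h.tolist()}"
                )
            net = float(profile.net[idx[0]])
        if net <= exclusion_tol:
            entries.append(RecoveryEntry(analyte, None, None, included=False))
            continue
        c_pct = (
            net * spec.carbon_atoms / substrate.n_c_umol * 100.0
            if spec.carbon_atoms > 0
            else None
        )
        e_pct = (
            net * spec.reducing_equivalents / substrate.n_r_umol * 100.0
            if spec.reducing_equivalents > 0
            else None
        )
        entries.append(RecoveryEntry(analyte, c_pct, e_pct))
    return RecoveryTable(substrate=substrate, entries=entries)


#: Carbon atoms and electrons of the ribose unit hydrolyzed from RNA.
RIBOSE_CARBONS = 5.0
RIBOSE_ELECTRONS = 20.0


def ribose_basis(table: RecoveryTable) -> tuple[float, float]:
    """Rescale RNA-treatment totals to an RNA-derived-ribose-only basis.

    Of each 9.5-carbon nucleotide unit only the 5 ribose carbons (and
    their 20 oxidation electrons) are counted as available substrate, so
    totals are divided by the ribose share of carbon and of electrons.
    """
    sub = table.substrate
    if sub.kind != "rna" or not sub.carbon_per_unit:
        raise BalanceError("ribose-basis rescaling applies to RNA substrates only")
    carbon_share = RIBOSE_CARBONS / sub.carbon_per_unit
    electron_share = RIBOSE_ELECTRONS / (sub.n_r_c * sub.carbon_per_unit)
    return (
        table.total_carbon_pct / carbon_share,
        table.total_electron_pct / electron_share,
    )
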