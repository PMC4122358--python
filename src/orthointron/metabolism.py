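"""Routine metabolic rate from closed-chamber respirometry.

A fish sits in a sealed, stirred chamber while an oxygen probe records the
falling oxygen content.  The chain of computation is

    pO2 = (AP - SVP) * 0.2096          partial pressure of O2, kPa
    [O2] = pO2 * alpha                 concentration, mg/L
    total O2 = [O2] * volume * 1000    chamber content, ug
    rate = -slope(total O2 vs t)       consumption, ug/h (OLS)
    MR0 = rate / 1000 / mass           mass-specific, mgO2 kg^-1 h^-1
    MR = MR0 * exp(E / (k T))          Boltzmann temperature correction

where AP is atmospheric pressure (kPa), SVP the saturated vapour pressure of
water at the measurement temperature, 0.2096 the O2 fraction of air, alpha
the oxygen solubility (mg L^-1 kPa^-1) at the temperature and salinity of
measurement, E the activation energy of metabolic processes (0.65 eV by
default) and k the Boltzmann constant (8.62e-5 eV/K).  Traces whose total
oxygen falls by more than 20% are flagged invalid, mirroring standard
closed-respirometry practice; an initial fraction of the trace can be
trimmed to skip the probe/animal adaptation period.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps

from .errors import ParameterError, QualityError

O2_FRACTION_AIR = 0.2096
BOLTZMANN_EV_PER_K = 8.62e-5
DEFAULT_ACTIVATION_ENERGY_EV = 0.65
MAX_FALL_FRACTION = 0.20
DEFAULT_TRIM_FRACTION = 0.10


def partial_pressure_o2(ap_kpa: float, svp_kpa: float) -> float:
    """pO2 = (AP - SVP) * 0.2096, all in kPa.

    AP below SVP is physically impossible for an aerated chamber; equality
    is admitted as the degenerate limit (pO2 = 0).
    """
    if svp_kpa < 0:
        raise ParameterError("SVP must be non-negative")
    if ap_kpa < svp_kpa:
        raise ParameterError("atmospheric pressure below water vapour pressure")
    return (ap_kpa - svp_kpa) * O2_FRACTION_AIR


def oxygen_concentration(po2_kpa: float, alpha: float) -> float:
    """[O2] in mg/L from pO2 (kPa) and solubility alpha (mg L^-1 kPa^-1)."""
    if po2_kpa < 0 or alpha < 0:
        raise ParameterError("pO2 and alpha must be non-negative")
    return po2_kpa * alpha


@dataclass
class RespirometryTrace:
    """One closed-chamber recording plus the metadata needed to reduce it.

    ``readings`` are either percent air saturation (``reading_kind=
    'percent_saturation'``) or dissolved O2 concentration in mg/L
    (``'concentration'``); timestamps are hours.
    """

    timestamps: np.ndarray
    readings: np.ndarray
    chamber_volume_l: float
    water_temperature_c: float
    salinity_ppt: float
    ap_kpa: float
    svp_kpa: float
    alpha: float
    animal_mass_kg: float
    reading_kind: str = "percent_saturation"
    species_id: str = ""

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.readings = np.asarray(self.readings, dtype=float)
        if self.timestamps.size != self.readings.size:
            raise ParameterError("timestamps and readings differ in length")
        if self.timestamps.size < 10:
            raise ParameterError("a trace needs at least 10 points")
        if not np.all(np.diff(self.timestamps) > 0):
            raise ParameterError("timestamps must be strictly increasing")
        if self.chamber_volume_l <= 0 or self.animal_mass_kg <= 0:
            raise ParameterError("chamber volume and animal mass must be positive")
        if self.reading_kind not in {"percent_saturation", "concentration"}:
            raise ParameterError("reading_kind must be 'percent_saturation' or 'concentration'")

    def total_oxygen_ug(self) -> np.ndarray:
        """Chamber oxygen content (ug) at each timestamp."""
        if self.reading_kind == "percent_saturation":
            sat_conc = oxygen_concentration(
                partial_pressure_o2(self.ap_kpa, self.svp_kpa), self.alpha
            )
            conc = self.readings / 100.0 * sat_conc
        else:
            conc = self.readings
        return conc * self.chamber_volume_l * 1000.0


@dataclass(frozen=True)
class ConsumptionFit:
    rate_ug_per_h: float
    r_squared: float
    fall_fraction: float
    valid: bool
    n_points_used: int


def consumption_rate(
    trace: RespirometryTrace,
    trim_fraction: float = DEFAULT_TRIM_FRACTION,
    max_fall: float = MAX_FALL_FRACTION,
) -> ConsumptionFit:
    """OLS slope of total chamber oxygen vs time, negated to a consumption rate.

    The first ``trim_fraction`` of points is discarded (adaptation period).
    Traces whose oxygen content falls by more than ``max_fall`` are returned
    flagged invalid; a non-falling trace (slope >= 0) raises
    :class:`QualityError` as a gross artifact.
    """
    if not 0 <= trim_fraction < 1:
        raise ParameterError("trim_fraction must lie in [0,1)")
    total = trace.total_oxygen_ug()
    start = int(math.floor(trim_fraction * total.size))
    t = trace.timestamps[start:]
    y = total[start:]
    if t.size < 3:
        raise ParameterError("too few points after trimming")
    fit = _sps.linregress(t, y)
    if fit.slope >= 0:
        raise QualityError("oxygen content not falling: slope >= 0")
    first, last = float(y[0]), float(y[-1])
    fall_fraction = (first - last) / first if first > 0 else float("nan")
    return ConsumptionFit(
        rate_ug_per_h=-float(fit.slope),
        r_squared=float(fit.rvalue) ** 2,
        fall_fraction=fall_fraction,
        valid=bool(fall_fraction <= max_fall),
        n_points_used=int(t.size),
    )


def mass_specific_rate(rate_ug_per_h: float, mass_kg: float) -> float:
    """mgO2 kg^-1 h^-1 from a whole-animal rate in ug/h."""
    if mass_kg <= 0:
        raise ParameterError("mass must be positive")
    return rate_ug_per_h / 1000.0 / mass_kg


def boltzmann_correct(
    mr0: float,
    t_celsius: float,
    e_ev: float = DEFAULT_ACTIVATION_ENERGY_EV,
    k_ev: float = BOLTZMANN_EV_PER_K,
) -> float:
    """MR = MR0 * exp(E / (k T)), T in kelvin.

    The correction factor decreases with temperature, so warm-water
    measurements are scaled up less than cold-water ones; at E = 0.65 eV it
    is numerically enormous (~1.5e11 at 20 C) but cancels in every ratio or
    rank statistic the analysis uses.
    """
    if mr0 <= 0:
        raise ParameterError("mr0 must be positive")
    if not -2.0 <= t_celsius <= 45.0:
        raise ParameterError("temperature outside the physically plausible range")
    t_kelvin = t_celsius + 273.15
    return mr0 * math.exp(e_ev / (k_ev * t_kelvin))


@dataclass(frozen=True)
class MRRecord:
    species_id: str
    mr0: float
    t_kelvin: float
    mr: float
    e_ev: float = DEFAULT_ACTIVATION_ENERGY_EV
    k_ev: float = BOLTZMANN_EV_PER_K


def metabolic_rate_record(
    trace: RespirometryTrace,
    trim_fraction: float = DEFAULT_TRIM_FRACTION,
    e_ev: float = DEFAULT_ACTIVATION_ENERGY_EV,
    require_valid: bool = True,
) -> MRRecord:
    """Full reduction of one trace to a temperature-corrected MR record."""
    fit = consumption_rate(trace, trim_fraction=trim_fraction)
    if require_valid and not fit.valid:
        raise QualityError(
            f"trace fell {fit.fall_fraction:.1%}, exceeding the allowed oxygen fall"
        )
    mr0 = mass_specific_rate(fit.rate_ug_per_h, trace.animal_mass_kg)
    mr = boltzmann_correct(mr0, trace.water_temperature_c, e_ev=e_ev)
    return MRRecord(
        species_id=trace.species_id,
        mr0=mr0,
        t_kelvin=trace.water_temperature_c + 273.15,
        mr=mr,
        e_ev=e_ev,
    )


# ---------------------------------------------------------------------------
# convenience tables (non-normative) and trace I/O
# ---------------------------------------------------------------------------

def freshwater_svp_kpa(t_celsius: float) -> float:
    """Saturated vapour pressure of fresh water (kPa), Magnus approximation.

    Convenience only: measured SVP/alpha for the actual temperature and
    salinity should be supplied whenever available.
    """
    return 0.61094 * math.exp(17.625 * t_celsius / (t_celsius + 243.04))


def freshwater_alpha(t_celsius: float) -> float:
    """Approximate O2 solubility of fresh water in mg L^-1 kPa^-1.

    Quadratic fit to standard solubility tables over 0-35 C; convenience
    only, not a calibration.
    """
    return 0.6896 - 0.01646 * t_celsius + 0.000197 * t_celsius**2


def read_trace_tsv(
    path: str | os.PathLike,
    **metadata,
) -> RespirometryTrace:
    """Load a two-column TSV (time_h, reading) plus keyword metadata."""
    t, y = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("time"):
                continue
            a, b = line.split("\t")
            t.append(float(a))
            y.append(float(b))
    return RespirometryTrace(timestamps=np.array(t), readings=np.array(y), **metadata)


def write_trace_tsv(trace: RespirometryTrace, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("time_h\treading\n")
        for t, y in zip(trace.timestamps, trace.readings):
            fh.write(f"{t:.6f}\t{y:.6f}\n")


def write_mr_records(records, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("species_id\tmr0\tt_kelvin\tmr\te_ev\n")
        for r in records:
            fh.write(f"{r.species_id}\t{r.mr0:.6f}\t{r.t_kelvin:.2f}\t{r.mr:.6e}\t{r.e_ev}\n")
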