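"""Synthetic relaxometry dilution series.

Rates follow ``R = intercept + r * C`` with optional Gaussian noise; the
raw-curve mode also emits the inversion-recovery and CPMG decay curves
implied by each concentration's T1/T2, using the 15-point inversion-time
protocol from 10 to 1000 ms.
"""

from __future__ import annotations

import numpy as np

from cerevasc.synthetic.seeds import substream

__all__ = ["generate_dilution_series", "DEFAULT_CONCENTRATIONS_MM", "ir_curve", "cpmg_curve"]

#: Six concentrations diluted down from 3 mM Gd.
DEFAULT_CONCENTRATIONS_MM = (0.0, 0.6, 1.2, 1.8, 2.4, 3.0)

#: The inversion-time protocol: 15 TIs from 10 to 1000 ms.
IR_INVERSION_TIMES_MS = tuple(np.linspace(10.0, 1000.0, 15))

#: CPMG echo-time protocol (ms): 32 echoes at 1.0 ms inter-echo spacing.
CPMG_ECHO_TIMES_MS = tuple(np.arange(1, 33) * 1.0)


def ir_curve(t1_ms: float, s0: float = 1.0, inversion_times_ms=IR_INVERSION_TIMES_MS) -> tuple[np.ndarray, np.ndarray]:
    """Magnitude inversion-recovery curve ``|S0 (1 - 2 exp(-TI/T1))|``."""
    ti = np.asarray(inversion_times_ms, dtype=float)
    return ti, np.abs(s0 * (1.0 - 2.0 * np.exp(-ti / t1_ms)))


def cpmg_curve(t2_ms: float, s0: float = 1.0, echo_times_ms=CPMG_ECHO_TIMES_MS) -> tuple[np.ndarray, np.ndarray]:
    """Mono-exponential CPMG decay ``S0 exp(-t/T2)``."""
    te = np.asarray(echo_times_ms, dtype=float)
    return te, s0 * np.exp(-te / t2_ms)


def generate_dilution_series(
    r1: float = 12.90,
    r2: float = 17.80,
    intercept_r1: float = 0.4,
    intercept_r2: float = 0.8,
    concentrations_mM=DEFAULT_CONCENTRATIONS_MM,
    noise_sd: float = 0.0,
    seed: int = 0,
    raw_curves: bool = False,
):
    """Return a :class:`~cerevasc.relaxometry.DilutionSeries` (plus raw curves).

    ``noise_sd`` is the SD (s^-1) of Gaussian noise added to each rate.
    With ``raw_curves=True`` also returns per-concentration
    ``(IRSeries, CpmgSeries)`` pairs generated from the noisy rates.
    """
    from cerevasc.relaxometry import CpmgSeries, DilutionSeries, IRSeries

    conc = np.asarray(concentrations_mM, dtype=float)
    if len(np.unique(conc)) < 2:
        raise ValueError("need at least two distinct concentrations")
    rng = substream(seed, "dilution")
    rates1 = intercept_r1 + r1 * conc
    rates2 = intercept_r2 + r2 * conc
    if noise_sd > 0:
        rates1 = rates1 + rng.normal(0.0, noise_sd, size=conc.shape)
        rates2 = rates2 + rng.normal(0.0, noise_sd, size=conc.shape)
    rates1 = np.clip(rates1, 1e-6, None)
    rates2 = np.clip(rates2, 1e-6, None)
    series = DilutionSeries(
        concentrations_mM=conc, t1_ms=1000.0 / rates1, t2_ms=1000.0 / rates2
    )
    if not raw_curves:
        return series
    curves = []
    for t1, t2 in zip(series.t1_ms, series.t2_ms):
        ti, s_ir = ir_curve(t1)
        te, s_cpmg = cpmg_curve(t2)
        curves.append(
            (
                IRSeries(inversion_times_ms=ti, signals=s_ir),
                CpmgSeries(echo_times_ms=te, signals=s_cpmg),
            )
        )
    return series, curves
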