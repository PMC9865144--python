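"""One-site isothermal-titration-calorimetry simulation and fitting.

Forward model
-------------
A syringe species X (concentration ``X0``) is injected in constant volumes
``v`` into a cell of volume ``V0`` containing the binding partner M at
``M0``.  Each injection displaces volume ``v`` from the cell, so total cell
concentrations follow the perfusion recurrence with ``f = v / V0``:

    M_i = M_{i-1} (1 - f)
    X_i = X_{i-1} (1 - f) + f X0

Binding of X to ``N`` equivalent sites on M with dissociation constant
``Kd`` gives the bound concentration as the physical root of the one-site
quadratic (``b <= min(X_i, N M_i)``):

    b_i = [ (X_i + N M_i + Kd) - sqrt((X_i + N M_i + Kd)^2 - 4 X_i N M_i) ] / 2

The heat evolved by injection ``i`` accounts for the bound complex carried
out of the cell by displacement and is normalized per mole of injectant
(``v X0`` moles per shot), plus a constant baseline offset:

    q_i = dH * V0 * (b_i - (1 - f) b_{i-1}) / (v X0) + offset     [kcal/mol]

Fitting
-------
``OneSiteModel`` follows the model/results idiom: construct from a measured
(or simulated) curve plus its protocol, call :meth:`OneSiteModel.fit`, and
read estimates, standard errors and diagnostics off the returned
:class:`OneSiteFitResults`.  The optimizer is bounded nonlinear least
squares with Kd log-parameterized (positivity and scale invariance);
standard errors come from the Jacobian at the optimum.  A c-value
``N M0 / Kd`` below 1 flags the fit as low-c (the isotherm is too shallow
for a well-conditioned fit; a wider protocol is suggested).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares


class NoSignalError(ValueError):
    """Raised when a curve carries no measurable heat."""


@dataclass(frozen=True)
class TitrationProtocol:
    """Instrument protocol.  Defaults: 200 uL cell, 40 uM in-cell, 400 uM
    syringe, 19 x 3 uL injections at 25 C (titrant in excess)."""

    cell_volume_l: float = 200e-6
    cell_conc_m: float = 40e-6
    syringe_conc_m: float = 400e-6
    injection_volume_l: float = 3e-6
    n_injections: int = 19
    temperature_k: float = 298.15

    def __post_init__(self) -> None:
        for name in ("cell_volume_l", "cell_conc_m", "syringe_conc_m",
                     "injection_volume_l", "n_injections", "temperature_k"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.syringe_conc_m <= self.cell_conc_m:
            raise ValueError("syringe concentration must exceed cell concentration")

    def total_concentrations(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-injection total (X_i, M_i) in the cell, molar."""
        f = self.injection_volume_l / self.cell_volume_l
        n = self.n_injections
        i = np.arange(1, n + 1)
        m = self.cell_conc_m * (1.0 - f) ** i
        x = self.syringe_conc_m * (1.0 - (1.0 - f) ** i)
        return x, m


@dataclass(frozen=True)
class TitrationCurve:
    """Per-injection heats (kcal per mole of injectant) and molar ratios X/M."""

    heats: np.ndarray
    molar_ratio: np.ndarray

    def __post_init__(self) -> None:
        heats = np.asarray(self.heats, dtype=float)
        ratio = np.asarray(self.molar_ratio, dtype=float)
        if heats.shape != ratio.shape or heats.ndim != 1:
            raise ValueError("heats and molar_ratio must be 1-D arrays of equal length")
        if not np.all(np.isfinite(heats)):
            raise ValueError("heats must be finite")
        if np.any(np.diff(ratio) <= 0):
            raise ValueError("molar ratio must be strictly increasing")
        object.__setattr__(self, "heats", heats)
        object.__setattr__(self, "molar_ratio", ratio)

    def __len__(self) -> int:
        return len(self.heats)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "injection_index": np.arange(1, len(self) + 1),
                "heat_kcal_per_mol": self.heats,
                "molar_ratio": self.molar_ratio,
            }
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TitrationCurve":
        df = pd.read_csv(path, sep="\t")
        return cls(
            heats=df["heat_kcal_per_mol"].to_numpy(),
            molar_ratio=df["molar_ratio"].to_numpy(),
        )


def _bound_concentration(x: np.ndarray, m: np.ndarray, n_sites: float, kd: float) -> np.ndarray:
    """Physical root of the one-site quadratic: bound <= min(x, n*m)."""
    sites = n_sites * m
    s = x + sites + kd
    disc = np.maximum(s * s - 4.0 * x * sites, 0.0)
    return 0.5 * (s - np.sqrt(disc))


def model_heats(
    protocol: TitrationProtocol,
    n_sites: float,
    kd: float,
    dh: float,
    offset: float = 0.0,
) -> np.ndarray:
    """Noise-free per-injection heats (kcal/mol injectant) for one-site binding."""
    f = protocol.injection_volume_l / protocol.cell_volume_l
    x, m = protocol.total_concentrations()
    b = _bound_concentration(x, m, n_sites, kd)
    b_prev = np.concatenate([[0.0], b[:-1]])
    moles_new = protocol.cell_volume_l * (b - (1.0 - f) * b_prev)
    per_mole = moles_new / (protocol.injection_volume_l * protocol.syringe_conc_m)
    return dh * per_mole + offset


def simulate_titration(
    protocol: TitrationProtocol,
    n_sites: float,
    kd: float,
    dh: float,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> TitrationCurve:
    """Simulate a one-site titration, optionally with Gaussian heat noise.

    ``noise_sd`` is an absolute standard deviation in kcal/mol of injectant;
    use :func:`relative_noise_sd` to express it as a fraction of the first
    injection's heat.  Seeded for reproducibility.
    """
    if kd <= 0:
        raise ValueError("Kd must be positive")
    if n_sites <= 0:
        raise ValueError("stoichiometry N must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    heats = model_heats(protocol, n_sites, kd, dh)
    if noise_sd > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        heats = heats + rng.normal(0.0, noise_sd, size=heats.shape)
    x, m = protocol.total_concentrations()
    return TitrationCurve(heats=heats, molar_ratio=x / m)


def relative_noise_sd(
    protocol: TitrationProtocol, n_sites: float, kd: float, dh: float, fraction: float
) -> float:
    """Noise sd equal to ``fraction`` of the noise-free first-injection heat."""
    return abs(fraction * model_heats(protocol, n_sites, kd, dh)[0])


@dataclass
class OneSiteFitResults:
    """Estimates, uncertainties and diagnostics of a one-site fit."""

    n_sites: float
    kd: float
    dh: float
    offset: float
    se_n: float
    se_kd: float
    se_dh: float
    se_offset: float
    converged: bool
    singular: bool
    low_c: bool
    c_value: float
    ssr: float
    residuals: np.ndarray
    n_obs: int
    message: str = ""

    @property
    def kd_um(self) -> float:
        return self.kd * 1e6

    def summary(self) -> str:
        lines = [
            "One-site binding fit",
            "=" * 46,
            f"{'observations':<22}{self.n_obs:>24}",
            f"{'converged':<22}{str(self.converged):>24}",
            f"{'c-value (N*M0/Kd)':<22}{self.c_value:>24.3g}",
            f"{'residual SSQ':<22}{self.ssr:>24.4g}",
            "-" * 46,
            f"{'parameter':<12}{'estimate':>16}{'std err':>16}",
            f"{'N':<12}{self.n_sites:>16.4g}{self.se_n:>16.3g}",
            f"{'Kd [M]':<12}{self.kd:>16.4g}{self.se_kd:>16.3g}",
            f"{'dH [kcal/mol]':<12}{self.dh:>15.4g}{self.se_dh:>16.3g}",
            f"{'offset':<12}{self.offset:>16.4g}{self.se_offset:>16.3g}",
            "=" * 46,
        ]
        if self.low_c:
            lines.append(
                "warning: c < 1 (shallow isotherm); consider higher cell "
                "concentration or more injections"
            )
        if self.message:
            lines.append(self.message)
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "n_sites": self.n_sites,
            "kd_m": self.kd,
            "kd_um": self.kd_um,
            "dh_kcal_per_mol": self.dh,
            "offset_kcal_per_mol": self.offset,
            "se": {"n_sites": self.se_n, "kd_m": self.se_kd, "dh": self.se_dh, "offset": self.se_offset},
            "converged": self.converged,
            "singular": self.singular,
            "low_c": self.low_c,
            "c_value": self.c_value,
            "ssr": self.ssr,
            "n_obs": self.n_obs,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


class OneSiteModel:
    """One-site binding model bound to a titration curve and its protocol."""

    MIN_INJECTIONS = 6

    def __init__(self, curve: TitrationCurve, protocol: TitrationProtocol):
        if len(curve) < self.MIN_INJECTIONS:
            raise ValueError(f"need at least {self.MIN_INJECTIONS} injections, got {len(curve)}")
        if len(curve) != protocol.n_injections:
            raise ValueError(
                f"curve has {len(curve)} injections but protocol specifies {protocol.n_injections}"
            )
        self.curve = curve
        self.protocol = protocol

    def _initial_params(self) -> np.ndarray:
        # N = 1, dH = first-injection heat, Kd = M0/10, offset = 0.
        dh0 = float(self.curve.heats[0])
        kd0 = self.protocol.cell_conc_m / 10.0
        return np.array([1.0, math.log(kd0), dh0, 0.0])

    def _residuals(self, params: np.ndarray) -> np.ndarray:
        n_sites, log_kd, dh, offset = params
        pred = model_heats(self.protocol, n_sites, math.exp(log_kd), dh, offset)
        return pred - self.curve.heats

    def fit(self, init: Sequence[float] | None = None) -> OneSiteFitResults:
        """Bounded nonlinear least squares on the per-injection heats.

        ``init`` optionally overrides the default start (N, Kd [M], dH,
        offset).  All-zero heats raise :class:`NoSignalError`; a singular
        Jacobian is flagged on the results, never silent.
        """
        heats = self.curve.heats
        if float(np.max(np.abs(heats))) < 1e-12:
            raise NoSignalError("no signal: all injection heats are zero")

        if init is None:
            x0 = self._initial_params()
        else:
            n0, kd0, dh0, off0 = init
            x0 = np.array([n0, math.log(kd0), dh0, off0])
        lower = [1e-3, math.log(1e-15), -np.inf, -np.inf]
        upper = [1e3, math.log(1.0), np.inf, np.inf]
        x0 = np.clip(x0, lower, upper)

        res = least_squares(self._residuals, x0, bounds=(lower, upper), method="trf")
        n_sites, log_kd, dh, offset = res.x
        kd = math.exp(log_kd)
        ssr = float(2.0 * res.cost)
        dof = max(len(heats) - 4, 1)
        sigma2 = ssr / dof

        singular = False
        try:
            jtj = res.jac.T @ res.jac
            cov = np.linalg.inv(jtj) * sigma2
            se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        except np.linalg.LinAlgError:
            singular = True
            se = np.full(4, np.nan)
        if not np.all(np.isfinite(se)):
            singular = True

        c_value = n_sites * self.protocol.cell_conc_m / kd
        return OneSiteFitResults(
            n_sites=float(n_sites),
            kd=float(kd),
            dh=float(dh),
            offset=float(offset),
            se_n=float(se[0]),
            se_kd=float(kd * se[1]),  # delta method from log-parameterization
            se_dh=float(se[2]),
            se_offset=float(se[3]),
            converged=bool(res.success),
            singular=singular,
            low_c=bool(c_value < 1.0),
            c_value=float(c_value),
            ssr=ssr,
            residuals=res.fun.copy(),
            n_obs=len(heats),
            message="" if res.success else res.message,
        )


def fit_one_site(
    curve: TitrationCurve,
    protocol: TitrationProtocol,
    init: Sequence[float] | None = None,
) -> OneSiteFitResults:
    """Convenience wrapper: ``OneSiteModel(curve, protocol).fit(init)``."""
    return OneSiteModel(curve, protocol).fit(init)


def read_protocol(path: str | Path) -> TitrationProtocol:
    """Read a protocol from a YAML or JSON mapping of field names."""
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        import yaml

        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    return TitrationProtocol(**data)
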