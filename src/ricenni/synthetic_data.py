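"""Synthetic two-experiment rice dataset with known nitrogen ground truth.

No field data accompany the method this package implements, so every stage is
exercised on a generator that emulates the field design: two experiments with
five N fertilization gradients each (0–300 and 0–200 kg/hm²), eight sampling
days from tillering to heading, and replicated plots, giving roughly 200
plot-day samples with paired agronomy records and canopy reflectance spectra.

The agronomy generator is built around the dilution-curve geometry itself:

* AGB grows logistically in the day index with a gradient-dependent asymptote;
  the top two gradients share one asymptote, producing the biomass plateau the
  critical-curve procedure requires.
* Within each day, the N-limited gradients' N concentration lies (before
  noise) on a positive-slope line through the day's critical point
  ``(agb_plateau, a * agb_plateau**(-b))`` — the geometry the five-step
  procedure assumes — so with noise switched off the procedure recovers the
  generating (a, b) exactly.
* Plateau gradients draw latent NNI >= 1; the latent NNI of every sample is
  the ratio of its (noisy) N concentration to the true critical concentration,
  so ``n_conc / (a * agb**(-b))`` equals the stored latent NNI by definition.

The spectral generator is phenomenological, not radiative-transfer: an
AGB-driven near-infrared plateau joined through a logistic red edge
(~680–750 nm) to a low visible baseline with a green peak at 550 nm, minus
chlorophyll absorption wells at 430 and 660 nm whose depth grows with a canopy
chlorophyll proxy (N concentration × AGB). It guarantees the monotonicity a
nitrogen-sensitive canopy shows: more N → deeper 660 nm absorption, more
biomass → higher NIR reflectance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_agronomy",
    "simulate_spectra",
    "simulate_two_experiments",
    "EXPERIMENT1_RATES",
    "EXPERIMENT2_RATES",
]

EXPERIMENT1_RATES = (0.0, 75.0, 150.0, 225.0, 300.0)
EXPERIMENT2_RATES = (0.0, 50.0, 100.0, 150.0, 200.0)

#: Default AGB asymptotes (t/hm²) per gradient; top two equal = plateau.
_DEFAULT_ASYMPTOTES = (3.0, 5.0, 6.5, 7.5, 7.5)


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of the synthetic dataset (one experiment).

    Defaults mirror the first field experiment: five N rates 0–300 kg/hm²,
    eight sampling days at nine-day intervals, three replicate plots per
    gradient, and the published dilution curve a=2.03, b=0.46.
    """

    experiment: str = "exp1"
    n_rates: tuple = EXPERIMENT1_RATES
    n_days: int = 8
    plots_per_gradient: int = 3
    dilution_a: float = 2.03
    dilution_b: float = 0.46
    agb_asymptotes: tuple = _DEFAULT_ASYMPTOTES
    #: fraction of Nc(agb_plateau) lost per unit relative biomass shortfall
    #: along the within-day N-limited line (sets how deep deficit NNIs go).
    deficit_slope: float = 0.5
    #: latent NNI band of the plateau (non-limited) gradients.
    rich_nni_band: tuple = (1.0, 1.3)
    noise_sd_agb: float = 0.05     # relative (lognormal sigma)
    noise_sd_n: float = 0.05       # relative (lognormal sigma)
    spectral_noise_sd: float = 0.002  # reflectance units, additive
    wavelength_min: float = 400.0
    wavelength_max: float = 1000.0
    wavelength_step: float = 1.0
    force_standard_sample: bool = True
    growth_rate: float = 0.8       # logistic steepness per day index
    growth_midpoint: float = 4.0   # day index of the inflection
    seed: int = 0

    def __post_init__(self) -> None:
        rates = tuple(self.n_rates)
        if len(rates) < 2 or any(b <= a for a, b in zip(rates, rates[1:])):
            raise ValueError("n_rates must be strictly increasing with >= 2 rates")
        if len(self.agb_asymptotes) != len(rates):
            raise ValueError("need one AGB asymptote per N rate")
        if self.dilution_a <= 0 or not (0.0 < self.dilution_b < 1.0):
            raise ValueError("dilution_a must be > 0 and dilution_b in (0, 1)")
        if min(self.noise_sd_agb, self.noise_sd_n, self.spectral_noise_sd) < 0:
            raise ValueError("noise scales must be non-negative")
        if self.wavelength_min >= self.wavelength_max:
            raise ValueError("wavelength_min must be below wavelength_max")
        if self.plots_per_gradient <= 0:
            raise ValueError("plots_per_gradient must be positive")
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")

    @property
    def wavelengths(self) -> np.ndarray:
        return np.arange(self.wavelength_min, self.wavelength_max + 1e-9,
                         self.wavelength_step)


@dataclass
class SimTruth:
    """Ground truth of a simulated dataset, for recovery tests."""

    true_a: float
    true_b: float
    latent_nni: dict = field(default_factory=dict)
    canopy_chlorophyll_proxy: dict = field(default_factory=dict)


def _logistic_fraction(day: np.ndarray, cfg: SimConfig) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-cfg.growth_rate * (day - cfg.growth_midpoint)))


def simulate_agronomy(config: SimConfig, seed: int | None = None
                      ) -> tuple[pd.DataFrame, SimTruth]:
    """Generate one experiment's plot-day agronomy table plus its ground truth.

    Returns a DataFrame with columns ``sample_id, experiment, gradient, plot,
    day, n_rate_kg_hm2, agb_t_hm2, n_conc_pct`` (one row per gradient × plot ×
    day) and the matching :class:`SimTruth`. Identical ``seed`` (and config)
    gives bit-identical output.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    a, b = config.dilution_a, config.dilution_b
    n_grad = len(config.n_rates)
    plateau = max(config.agb_asymptotes)

    rows = []
    truth = SimTruth(true_a=a, true_b=b)
    for day in range(1, config.n_days + 1):
        frac = float(_logistic_fraction(np.array(day, float), config))
        agb_nl = plateau * frac                      # day's non-limited biomass
        nc_nl = a * agb_nl ** (-b)                   # day's critical N%
        slope = config.deficit_slope * nc_nl / agb_nl
        day_rows = []
        for g, (rate, asym) in enumerate(zip(config.n_rates, config.agb_asymptotes)):
            limited = asym < plateau
            for p in range(config.plots_per_gradient):
                agb0 = asym * frac
                agb = agb0 * float(np.exp(rng.normal(0.0, config.noise_sd_agb)))
                if limited:
                    n_clean = nc_nl - slope * (agb_nl - agb)
                else:
                    nni_draw = float(rng.uniform(*config.rich_nni_band))
                    n_clean = nni_draw * a * agb ** (-b)
                n_conc = max(n_clean, 1e-6) * float(
                    np.exp(rng.normal(0.0, config.noise_sd_n)))
                sid = f"{config.experiment}-d{day}-g{g}-p{p}"
                day_rows.append([sid, config.experiment, f"N{g}", p, day,
                                 rate, agb, n_conc])
        if config.force_standard_sample:
            # overwrite the first plateau-gradient plot: exact near-critical NNI
            top_g = int(np.argmax(config.agb_asymptotes))
            idx = next(i for i, r in enumerate(day_rows)
                       if r[2] == f"N{top_g}" and r[3] == 0)
            nni_std = float(rng.uniform(0.991, 1.009))
            agb_std = day_rows[idx][6]
            day_rows[idx][7] = nni_std * a * agb_std ** (-b)
        rows.extend(day_rows)

    df = pd.DataFrame(rows, columns=[
        "sample_id", "experiment", "gradient", "plot", "day",
        "n_rate_kg_hm2", "agb_t_hm2", "n_conc_pct"])
    nc_true = a * df["agb_t_hm2"].to_numpy() ** (-b)
    nni = df["n_conc_pct"].to_numpy() / nc_true
    proxy = df["n_conc_pct"].to_numpy() * df["agb_t_hm2"].to_numpy()
    truth.latent_nni = dict(zip(df["sample_id"], nni))
    truth.canopy_chlorophyll_proxy = dict(zip(df["sample_id"], proxy))
    return df, truth


def _canopy_reflectance(wl: np.ndarray, agb: float, chloro: float) -> np.ndarray:
    """Noise-free phenomenological canopy reflectance on wavelength grid ``wl``."""
    nir = 0.28 + 0.32 * (1.0 - np.exp(-agb / 4.5))
    red_edge = 1.0 / (1.0 + np.exp(-(wl - 715.0) / 12.0))
    green = 0.04 * np.exp(-((wl - 550.0) ** 2) / (2.0 * 22.0**2))
    well_depth = 0.045 * (1.0 - np.exp(-chloro / 4.0))
    wells = well_depth * (np.exp(-((wl - 660.0) ** 2) / (2.0 * 28.0**2))
                          + 0.7 * np.exp(-((wl - 430.0) ** 2) / (2.0 * 25.0**2)))
    return nir * red_edge + 0.05 + green - wells


def simulate_spectra(agronomy: pd.DataFrame, truth: SimTruth, config: SimConfig,
                     seed: int | None = None):
    """Generate a canopy :class:`~ricenni.spectra.SpectrumSet` for an agronomy table.

    Reflectance is the parametric canopy model plus additive Gaussian noise of
    sd ``config.spectral_noise_sd``, clipped to (0, 1]. Sample order and period
    labels follow the agronomy table.
    """
    from .spectra import SpectrumSet, period_labels

    if len(agronomy) == 0:
        raise ValueError("agronomy table is empty")
    missing = [sid for sid in agronomy["sample_id"]
               if sid not in truth.canopy_chlorophyll_proxy]
    if missing:
        raise ValueError(f"sample ids absent from truth: {missing[:5]}")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    wl = config.wavelengths
    refl = np.empty((len(agronomy), wl.size))
    for i, row in enumerate(agronomy.itertuples(index=False)):
        chloro = truth.canopy_chlorophyll_proxy[row.sample_id]
        refl[i] = _canopy_reflectance(wl, row.agb_t_hm2, chloro)
    if config.spectral_noise_sd > 0:
        refl = refl + rng.normal(0.0, config.spectral_noise_sd, size=refl.shape)
    refl = np.clip(refl, 1e-6, 1.0)
    return SpectrumSet(wavelengths=wl, reflectance=refl,
                       sample_ids=list(agronomy["sample_id"]),
                       periods=period_labels(agronomy))


def simulate_two_experiments(seed: int, cfg1: SimConfig | None = None,
                             cfg2: SimConfig | None = None):
    """Combined two-experiment dataset (~200 plot-day samples).

    Experiment 1: rates 0/75/150/225/300 kg/hm², 3 plots per gradient (120
    samples); experiment 2: rates 0/50/100/150/200 kg/hm², 2 plots per
    gradient (80 samples). Returns ``(agronomy, truth, spectra)`` with the two
    experiments concatenated; sub-seeds derive deterministically from ``seed``.
    """
    if cfg1 is None:
        cfg1 = SimConfig(experiment="exp1")
    if cfg2 is None:
        cfg2 = SimConfig(experiment="exp2", n_rates=EXPERIMENT2_RATES,
                         plots_per_gradient=2)
    s1, s2, s3, s4 = np.random.SeedSequence(seed).generate_state(4) % (2**31)
    ag1, t1 = simulate_agronomy(cfg1, seed=int(s1))
    ag2, t2 = simulate_agronomy(cfg2, seed=int(s2))
    sp1 = simulate_spectra(ag1, t1, cfg1, seed=int(s3))
    sp2 = simulate_spectra(ag2, t2, cfg2, seed=int(s4))
    agronomy = pd.concat([ag1, ag2], ignore_index=True)
    truth = SimTruth(true_a=cfg1.dilution_a, true_b=cfg1.dilution_b,
                     latent_nni={**t1.latent_nni, **t2.latent_nni},
                     canopy_chlorophyll_proxy={**t1.canopy_chlorophyll_proxy,
                                               **t2.canopy_chlorophyll_proxy})
    spectra = sp1.concat(sp2)
    return agronomy, truth, spectra
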