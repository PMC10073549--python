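"""End-to-end NNI estimation pipeline: data I/O, splitting, metrics, orchestration.

``run_full_pipeline`` executes the whole analysis on synthetic or loaded data:

    agronomy → critical-N curve → NNI → spectral preprocessing → per-period
    standard spectra → {original, log, difference, logdifference} transforms →
    sparse-AE features → ELM and BES-ELM regression → R²/RMSE + NNI-group
    stratified evaluation,

producing one :class:`EvalReport` per (transform, model) pair — eight in
total — with seeded bit-reproducibility.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import agronomy as agro
from . import features as feat
from . import models as mdl
from . import spectra as spec
from .synthetic_data import simulate_two_experiments

logger = logging.getLogger(__name__)

__all__ = [
    "SplitSpec",
    "PredictionSet",
    "GroupMetrics",
    "EvalReport",
    "PipelineConfig",
    "load_tables",
    "split_dataset",
    "r_squared",
    "rmse",
    "group_metrics",
    "fit_curve_from_agronomy",
    "run_full_pipeline",
]

AGRONOMY_COLUMNS = ["sample_id", "experiment", "gradient", "plot", "day",
                    "n_rate_kg_hm2", "agb_t_hm2", "n_conc_pct"]


# --------------------------------------------------------------------------
# metrics

@dataclass
class PredictionSet:
    """Paired measured (y) and estimated (yhat) NNI values."""

    sample_ids: list
    y: np.ndarray
    yhat: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.yhat = np.asarray(self.yhat, dtype=float)
        if self.y.shape != self.yhat.shape or len(self.sample_ids) != self.y.size:
            raise ValueError("sample_ids, y and yhat must have equal lengths")

    @property
    def n(self) -> int:
        return self.y.size


def r_squared(p: PredictionSet) -> float:
    """Coefficient of determination, 1 − SSres/SStot."""
    if p.n < 2:
        raise ValueError("R² needs at least 2 samples")
    sstot = float(np.sum((p.y - p.y.mean()) ** 2))
    if sstot == 0:
        raise ValueError("R² undefined: zero variance in measured values")
    return 1.0 - float(np.sum((p.y - p.yhat) ** 2)) / sstot


def rmse(p: PredictionSet) -> float:
    """Root mean square error of the estimates."""
    if p.n < 1:
        raise ValueError("RMSE needs at least 1 sample")
    return float(np.sqrt(np.mean((p.y - p.yhat) ** 2)))


@dataclass
class GroupMetrics:
    """Metrics inside one NNI group; ``defined`` is False for n < 3 or flat y."""

    n: int
    r2: float | None
    rmse: float | None
    defined: bool


def group_metrics(p: PredictionSet, groups) -> dict:
    """R²/RMSE stratified by measured-NNI group (``deficit`` NNI<1, ``rich`` NNI>=1).

    Groups with fewer than 3 samples or zero variance in the measured values
    are flagged undefined instead of reporting a number. Group sizes always
    sum to the evaluated set size.
    """
    groups = np.asarray(groups)
    if groups.shape[0] != p.n:
        raise ValueError("groups length must match prediction set size")
    out = {}
    for name in ("deficit", "rich"):
        mask = groups == name
        n = int(mask.sum())
        if n < 3 or np.ptp(p.y[mask]) == 0:
            out[name] = GroupMetrics(n=n, r2=None, rmse=None, defined=False)
            continue
        sub = PredictionSet([s for s, m in zip(p.sample_ids, mask) if m],
                            p.y[mask], p.yhat[mask])
        out[name] = GroupMetrics(n=n, r2=r_squared(sub), rmse=rmse(sub),
                                 defined=True)
    return out


# --------------------------------------------------------------------------
# loading and splitting

def load_tables(agronomy_path, spectra_path):
    """Load and join the agronomy and spectra CSVs on ``sample_id``.

    Returns ``(agronomy, spectra, unmatched)`` where ``unmatched`` lists the
    sample ids present in only one of the two files (also logged); the
    returned tables contain the joined samples in agronomy order.
    """
    agronomy = pd.read_csv(agronomy_path)
    missing = [c for c in AGRONOMY_COLUMNS if c not in agronomy.columns]
    if missing:
        raise ValueError(f"agronomy CSV missing columns: {missing}")
    for col in ("agb_t_hm2", "n_conc_pct", "n_rate_kg_hm2"):
        if not np.issubdtype(agronomy[col].dtype, np.number):
            raise ValueError(f"non-numeric values in column {col!r}")
    dup = agronomy["sample_id"][agronomy["sample_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate sample_id in agronomy table: {dup.iloc[0]!r}")
    sset = spec.read_spectra_csv(spectra_path)
    if len(set(sset.sample_ids)) != len(sset.sample_ids):
        seen, d = set(), None
        for s in sset.sample_ids:
            if s in seen:
                d = s
                break
            seen.add(s)
        raise ValueError(f"duplicate sample_id in spectra table: {d!r}")

    ag_ids, sp_ids = set(agronomy["sample_id"]), set(sset.sample_ids)
    unmatched = sorted((ag_ids - sp_ids) | (sp_ids - ag_ids), key=str)
    if unmatched:
        logger.warning("%d sample ids unmatched between tables: %s",
                       len(unmatched), unmatched[:10])
    keep = agronomy["sample_id"].isin(sp_ids)
    agronomy = agronomy[keep].reset_index(drop=True)
    idx = [sset.sample_ids.index(s) for s in agronomy["sample_id"]]
    sset = spec.SpectrumSet(sset.wavelengths, sset.reflectance[idx],
                            list(agronomy["sample_id"]),
                            spec.period_labels(agronomy))
    return agronomy, sset, unmatched


@dataclass(frozen=True)
class SplitSpec:
    """Train/test split rule: fraction, stratification keys and seed."""

    train_fraction: float = 0.7
    stratify_by: tuple = ("period", "group")
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")


def split_dataset(samples: pd.DataFrame, split: SplitSpec,
                  pin_train: set | None = None):
    """Seeded stratified train/test split on ``sample_id``.

    Stratifies by the columns in ``split.stratify_by`` that are present; if
    any stratum has fewer than 2 samples the split falls back to a global
    (unstratified) one with a warning. Ids in ``pin_train`` are forced into
    the training set before the remainder is split. Train and test are always
    disjoint and exhaustive.
    """
    if len(samples) < 4:
        raise ValueError("need at least 4 samples to split")
    rng = np.random.default_rng(split.seed)
    pin_train = set(pin_train or ())
    keys = [k for k in split.stratify_by if k in samples.columns]
    if keys:
        strata = [sub for _, sub in samples.groupby(keys, sort=True)]
        if min(len(s) for s in strata) < 2:
            logger.warning("stratum with < 2 samples: falling back to global split")
            strata = [samples]
    else:
        strata = [samples]

    train, test = [], []
    for sub in strata:
        ids = list(sub["sample_id"])
        pinned = [s for s in ids if s in pin_train]
        pool = [s for s in ids if s not in pin_train]
        n_train = int(round(split.train_fraction * len(ids)))
        n_extra = max(n_train - len(pinned), 0)
        n_extra = min(n_extra, len(pool))
        order = rng.permutation(len(pool))
        train.extend(pinned)
        train.extend(pool[i] for i in order[:n_extra])
        test.extend(pool[i] for i in order[n_extra:])
    return train, test


# --------------------------------------------------------------------------
# orchestration

@dataclass
class EvalReport:
    """Evaluation of one (transform, model) pair on the train and test sets."""

    transform: str
    model: str
    n_features: int
    r2_train: float
    rmse_train: float
    r2_test: float
    rmse_test: float
    groups: dict = field(default_factory=dict)  # {"deficit"/"rich": GroupMetrics}

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class PipelineConfig:
    """All knobs of a full pipeline run (defaults = the synthetic study design)."""

    seed: int = 0
    # data source: CSV paths, or None → synthetic two-experiment dataset
    agronomy_path: str | None = None
    spectra_path: str | None = None
    # preprocessing
    denoise_sigma: float = 2.0
    standard_window: float = 0.01
    transforms: tuple = spec.TRANSFORM_KINDS
    # split
    train_fraction: float = 0.7
    # sparse autoencoder
    ae_candidates: tuple = (30,)
    ae_epochs: int = 300
    ae_learning_rate: float = 0.01
    ae_sparsity_target: float = 0.1
    ae_weight_decay: float = 0.001
    ae_sparsity_weight: float = 3.0
    # models
    n_hidden: int = 20
    bes_population: int = 12
    bes_iterations: int = 20
    # output
    out_dir: str | None = None
    write_intermediates: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("transforms", "ae_candidates"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _subseed(root: np.random.SeedSequence, *key) -> int:
    # crc32, not hash(): str hashing is salted per process and would break
    # cross-run reproducibility.
    digest = zlib.crc32("|".join(map(str, key)).encode())
    child = np.random.SeedSequence(entropy=root.entropy, spawn_key=(digest,))
    return int(child.generate_state(1)[0] % (2**31))


def fit_curve_from_agronomy(agronomy_df: pd.DataFrame, alpha: float = 0.05):
    """Five-step dilution-curve construction from a (possibly multi-experiment) table.

    Per-day partitions and critical points are computed within each experiment;
    the curve is fitted on experiment 1's points when several experiments are
    present (further experiments' points serve as validation diagnostics).
    Days whose fits are degenerate are skipped with a warning.

    Returns ``(curve, points, diagnostics)`` where ``diagnostics`` maps each
    experiment to the R² of the fitted curve over its points.
    """
    points_by_exp: dict = {}
    for (exp, day), sub in agronomy_df.groupby(["experiment", "day"], sort=True):
        try:
            part = agro.partition_n_limited(sub, alpha=alpha)
            point = agro.critical_point_for_day(sub, part)
        except (agro.DegenerateFitError, ValueError) as err:
            logger.warning("skipping %s day %s: %s", exp, day, err)
            continue
        points_by_exp.setdefault(exp, []).append(point)
    if not points_by_exp:
        raise agro.DegenerateFitError("no usable critical points in any experiment")
    fit_exp = sorted(points_by_exp)[0]
    curve = agro.fit_critical_curve(points_by_exp[fit_exp])
    diagnostics = {}
    for exp, pts in points_by_exp.items():
        nc = np.array([p.n_critical for p in pts])
        pred = np.asarray(curve.critical_n(np.array([p.agb_max for p in pts])))
        sstot = float(np.sum((nc - nc.mean()) ** 2))
        diagnostics[exp] = (1.0 - float(np.sum((nc - pred) ** 2)) / sstot
                            if sstot > 0 else float("nan"))
    all_points = [p for pts in points_by_exp.values() for p in pts]
    return curve, all_points, diagnostics


def run_full_pipeline(config: PipelineConfig) -> list[EvalReport]:
    """Execute the full 4-transform × 2-model comparison; returns 8 reports.

    Identical config (including seed) gives identical reports. When
    ``config.out_dir`` is set, the curve fit, per-sample NNI, predictions and
    reports are written there (plus transformed spectra and features when
    ``write_intermediates`` is on).
    """
    root = np.random.SeedSequence(config.seed)
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    # --- data
    if config.agronomy_path and config.spectra_path:
        agronomy_df, sset, _ = load_tables(config.agronomy_path, config.spectra_path)
    else:
        agronomy_df, _, sset = simulate_two_experiments(
            _subseed(root, "sim"))

    # --- critical curve and NNI
    curve, points, curve_diag = fit_curve_from_agronomy(agronomy_df)
    nni_table = agro.compute_nni_table(agronomy_df, curve)
    logger.info("dilution curve a=%.4f b=%.4f (fit R²=%.4f)", curve.a, curve.b,
                curve.r2)

    # --- preprocessing
    grid_is_integer_nm = (np.allclose(sset.wavelengths % 1.0, 0.0)
                          and np.allclose(np.diff(sset.wavelengths), 1.0))
    if not grid_is_integer_nm:
        sset = spec.resample_to_1nm(sset, sset.wavelengths[0], sset.wavelengths[-1])
    sset = spec.gaussian_denoise(sset, sigma=config.denoise_sigma)

    # --- per-period standard spectra
    standards = spec.select_standard_spectra(sset, nni_table,
                                             window=config.standard_window)
    pinned = {sid for s in standards.values() if not s.fallback_used
              for sid in s.contributing_ids}

    # --- split (standard-spectrum contributors pinned to the training side)
    sample_table = agronomy_df[["sample_id"]].copy()
    sample_table["period"] = sset.periods
    sample_table["group"] = nni_table["group"].to_numpy()
    train_ids, test_ids = split_dataset(
        sample_table, SplitSpec(train_fraction=config.train_fraction,
                                seed=_subseed(root, "split")),
        pin_train=pinned)
    assert not set(train_ids) & set(test_ids)
    assert not pinned & set(test_ids), "standard-spectrum samples leaked into test"
    id_index = {sid: i for i, sid in enumerate(sset.sample_ids)}
    tr = np.array([id_index[s] for s in train_ids])
    te = np.array([id_index[s] for s in test_ids])
    nni_map = dict(zip(nni_table["sample_id"], nni_table["nni"]))
    group_map = dict(zip(nni_table["sample_id"], nni_table["group"]))
    y = np.array([nni_map[s] for s in sset.sample_ids])

    reports: list[EvalReport] = []
    predictions = []
    for kind in config.transforms:
        transformed = spec.apply_transform(sset, standards, kind)
        scaler = feat.MinMaxScaler().fit(transformed.values[tr])
        x_all = scaler.transform(transformed.values)

        candidates = []
        for width in config.ae_candidates:
            ae_cfg = feat.AeConfig(
                n_features=int(width),
                sparsity_target=config.ae_sparsity_target,
                weight_decay=config.ae_weight_decay,
                sparsity_weight=config.ae_sparsity_weight,
                epochs=config.ae_epochs,
                learning_rate=config.ae_learning_rate,
                seed=_subseed(root, "ae", kind, int(width)))
            candidates.append((ae_cfg, feat.train_sparse_autoencoder(x_all[tr], ae_cfg)))
        ae_cfg, ae_model, _, ae_report = feat.select_feature_config(
            candidates, x_all[tr], y[tr], x_all[te], y[te])
        f_all = feat.encode(ae_model, x_all).values
        logger.info("%s: selected %d AE features", kind, ae_cfg.n_features)

        elm_seed = _subseed(root, "elm", kind)
        elm = mdl.elm_train(f_all[tr], y[tr], n_hidden=config.n_hidden,
                            seed=elm_seed)
        bes_cfg = mdl.BesConfig(population=config.bes_population,
                                iterations=config.bes_iterations,
                                seed=elm_seed)
        bes_elm, _, _ = mdl.bes_elm_train(f_all[tr], y[tr], f_all[te], y[te],
                                          n_hidden=config.n_hidden, cfg=bes_cfg)

        for name, model in (("elm", elm), ("bes-elm", bes_elm)):
            p_tr = PredictionSet(train_ids, y[tr], mdl.elm_predict(model, f_all[tr]))
            p_te = PredictionSet(test_ids, y[te], mdl.elm_predict(model, f_all[te]))
            groups_te = np.array([group_map[s] for s in test_ids])
            reports.append(EvalReport(
                transform=kind, model=name, n_features=ae_cfg.n_features,
                r2_train=r_squared(p_tr), rmse_train=rmse(p_tr),
                r2_test=r_squared(p_te), rmse_test=rmse(p_te),
                groups=group_metrics(p_te, groups_te)))
            for split_name, pset in (("train", p_tr), ("test", p_te)):
                for sid, yi, yh in zip(pset.sample_ids, pset.y, pset.yhat):
                    predictions.append([kind, name, sid, split_name,
                                        group_map[sid], yi, yh])

        if out_dir and config.write_intermediates:
            spec.write_spectra_csv(out_dir / f"spectra_{kind}.csv", transformed)
            pd.DataFrame(f_all, columns=[f"f_{j+1}" for j in range(f_all.shape[1])]
                         ).assign(sample_id=sset.sample_ids).to_csv(
                out_dir / f"features_{kind}.csv", index=False)

    assert len(reports) == len(config.transforms) * 2
    if out_dir:
        _write_outputs(out_dir, curve, curve_diag, points, nni_table,
                       predictions, reports)
    return reports


def _write_outputs(out_dir: Path, curve, curve_diag, points, nni_table,
                   predictions, reports) -> None:
    with open(out_dir / "critical_curve.json", "w") as fh:
        json.dump({"a": curve.a, "b": curve.b, "r2": curve.r2,
                   "rmse": curve.rmse, "per_experiment_r2": curve_diag,
                   "points": [{"day": str(p.day), "agb_max": p.agb_max,
                               "n_critical": p.n_critical} for p in points]},
                  fh, indent=2)
    nni_table.to_csv(out_dir / "nni.csv", index=False)
    pd.DataFrame(predictions, columns=["transform", "model", "sample_id",
                                       "split", "group", "y", "yhat"]
                 ).to_csv(out_dir / "predictions.csv", index=False)
    with open(out_dir / "reports.json", "w") as fh:
        json.dump([r.to_dict() for r in reports], fh, indent=2)
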