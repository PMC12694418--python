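"""Synthetic dot clouds and study tables with known ground truth.

Clouds are mixtures of trivariate Gaussian populations in log10(SSC, FL1,
FSC) space — i.e. log-normal in raw instrument units, matching log-scale
acquisition — plus an optional uniform noise floor below the gate, and a raw
FL1 acquisition threshold emulating the instrument cutoff.  Because the
components are Gaussian with known covariance, the true ellipsoid axis
lengths 2 sqrt(chi2 * lambda) are analytic, which makes every extraction
stage testable against truth.

A study draws many samples in duplicate along two independent latent
gradients — degree of evaporation and trophic status — that (i) load onto a
panel of 18 named environmental covariates and (ii) deform the cloud:
higher trophic state and evaporation widen the FL1 spread (taller
ellipsoids) and raise the probability of a second (and rarely third)
high-fluorescence population; trophic state also shifts the SSC centroid.
Defaults are chosen to mimic oligo-to-eutrophic lake surveys: 20 000 events
per replicate, FL1 threshold 500, ~80/20 simple/complex heterogeneity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ellipsoid import chi2_quantile
from .io import EventCloud

#: the 18 environmental covariates emitted for every study
ENV_COLUMNS = (
    "wind",
    "precipitation",
    "pct_forestry",
    "pct_grassland",
    "pct_water",
    "pct_natural",
    "pct_mines",
    "watershed_area",
    "lake_area",
    "WRT",
    "Twater",
    "DIC",
    "S275_295",
    "d_excess",
    "TN",
    "TP",
    "DO",
    "BA",
)


@dataclass
class Component:
    """One log-normal population of a cloud (Gaussian in log10 space)."""

    mean: np.ndarray  # (3,) log10 (SSC, FL1, FSC)
    cov: np.ndarray  # (3, 3) symmetric PSD
    mass: float

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        if self.mean.shape != (3,) or self.cov.shape != (3, 3):
            raise ValueError("component needs a 3-vector mean and 3x3 covariance")
        if not np.allclose(self.cov, self.cov.T):
            raise ValueError("component covariance must be symmetric")
        if np.any(np.linalg.eigvalsh(self.cov) < -1e-10):
            raise ValueError("component covariance must be PSD")


@dataclass
class CloudSpec:
    components: list[Component]
    n_events: int = 20_000
    noise_floor_fraction: float = 0.0
    noise_box: np.ndarray = field(
        default_factory=lambda: np.array([[1.0, 2.5], [1.8, 2.65], [1.0, 2.5]])
    )  # (3, 2) log10 low/high per channel; FL1 box sits below log10(500)
    fl1_threshold: float = 500.0
    seed: int = 0

    def __post_init__(self):
        masses = [c.mass for c in self.components]
        if not math.isclose(sum(masses), 1.0, abs_tol=1e-9):
            raise ValueError(f"mass fractions must sum to 1, got {sum(masses)}")
        if self.n_events < 1:
            raise ValueError("n_events must be >= 1")


def generate_cloud(
    spec: CloudSpec, sample_id: str = "", replicate_id: str = ""
) -> tuple[EventCloud, dict]:
    """Draw one cloud and return it with its ground-truth record.

    Truth carries per-component parameters, the analytic axis lengths
    2 sqrt(6.251 * lambda) per component, and the pooled mixture covariance
    (law of total covariance) with its axis lengths.
    """
    rng = np.random.default_rng(spec.seed)
    n_noise = int(round(spec.noise_floor_fraction * spec.n_events))
    n_signal = spec.n_events - n_noise

    masses = np.array([c.mass for c in spec.components])
    counts = rng.multinomial(n_signal, masses)
    parts = [
        rng.multivariate_normal(c.mean, c.cov, size=k, method="cholesky")
        for c, k in zip(spec.components, counts)
        if k > 0
    ]
    if n_noise > 0:
        box = np.asarray(spec.noise_box, dtype=float)
        noise = rng.uniform(box[:, 0], box[:, 1], size=(n_noise, 3))
        parts.append(noise)
    values = np.vstack(parts)
    values = values[rng.permutation(len(values))]

    # emulate the instrument acquisition threshold on raw FL1
    keep = 10.0 ** values[:, 1] >= spec.fl1_threshold
    values = values[keep]
    if len(values) == 0:
        raise ValueError("FL1 threshold removed every event: infeasible spec")

    crit = chi2_quantile(0.90, 3)
    mix_mean = np.sum(masses[:, None] * [c.mean for c in spec.components], axis=0)
    pooled = sum(
        m * (c.cov + np.outer(c.mean - mix_mean, c.mean - mix_mean))
        for m, c in zip(masses, spec.components)
    )
    truth = {
        "components": [
            {
                "mean": c.mean.copy(),
                "cov": c.cov.copy(),
                "mass": c.mass,
                "axis_lengths": 2.0 * np.sqrt(crit * np.diag(c.cov)),
            }
            for c in spec.components
        ],
        "pooled_mean": mix_mean,
        "pooled_cov": pooled,
        "pooled_axis_lengths": 2.0 * np.sqrt(crit * np.diag(pooled)),
        "n_populations": len(spec.components),
        "n_removed_by_threshold": int((~keep).sum()),
    }
    cloud = EventCloud(values=values, sample_id=sample_id, replicate_id=replicate_id)
    return cloud, truth


@dataclass
class EffectMap:
    """How the latent gradients deform the per-sample cloud parameters."""

    base_mean: np.ndarray = field(
        default_factory=lambda: np.array([3.3, 3.6, 3.2])
    )
    # whole-cloud log10 variances sized so ellipsoid volumes straddle the
    # small/medium/large bins (V roughly 1.5-4.5 across the gradients)
    base_var: np.ndarray = field(
        default_factory=lambda: np.array([0.10, 0.14, 0.09])
    )
    ssc_fl1_corr: float = 0.3
    # log-scale multipliers of the FL1 variance (ellipsoid height)
    fl1_var_trophic: float = 0.30
    fl1_var_evaporation: float = 0.30
    # SSC centroid shift per unit trophic gradient
    ssc_centroid_trophic: float = 0.15
    # logistic intercepts/slopes for a 2nd and 3rd population appearing
    p2_intercept: float = -1.5
    p2_trophic: float = 1.0
    p2_evaporation: float = 0.6
    p3_given_2: float = 0.06
    # offsets of the extra high-fluorescence (HNA-like) populations; in
    # complex samples the per-population spread shrinks so the peaks are
    # separated by several pooled SDs, as in real multi-population cytograms
    pop2_offset: np.ndarray = field(
        default_factory=lambda: np.array([0.3, 1.0, 0.2])
    )
    pop3_offset: np.ndarray = field(
        default_factory=lambda: np.array([0.5, 1.7, 0.35])
    )
    complex_var_shrink: tuple = (0.5, 0.35, 0.3)


@dataclass
class StudySpec:
    n_samples: int = 40
    n_events: int = 20_000
    n_replicates: int = 2
    noise_floor_fraction: float = 0.02
    env_noise_sd: float = 0.5
    effects: EffectMap = field(default_factory=EffectMap)
    seed: int = 0


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def _cloud_spec_for(
    evap: float, troph: float, study: StudySpec, rng: np.random.Generator, seed: int
) -> CloudSpec:
    eff = study.effects
    var = eff.base_var.copy()
    var[1] *= math.exp(eff.fl1_var_trophic * troph + eff.fl1_var_evaporation * evap)
    mean = eff.base_mean.copy()
    mean[0] += eff.ssc_centroid_trophic * troph
    cov = np.diag(var)
    cov[0, 1] = cov[1, 0] = eff.ssc_fl1_corr * math.sqrt(var[0] * var[1])

    p2 = _sigmoid(eff.p2_intercept + eff.p2_trophic * troph + eff.p2_evaporation * evap)
    s1, s2, s3 = eff.complex_var_shrink
    comps: list[Component]
    if rng.random() < p2:
        if rng.random() < eff.p3_given_2:
            masses = (0.55, 0.30, 0.15)
            comps = [
                Component(mean, cov * s1, masses[0]),
                Component(mean + eff.pop2_offset, cov * s2, masses[1]),
                Component(mean + eff.pop3_offset, cov * s3, masses[2]),
            ]
        else:
            m2 = float(rng.uniform(0.15, 0.45))
            comps = [
                Component(mean, cov * s1, 1.0 - m2),
                Component(mean + eff.pop2_offset, cov * s2, m2),
            ]
    else:
        comps = [Component(mean, cov, 1.0)]
    return CloudSpec(
        components=comps,
        n_events=study.n_events,
        noise_floor_fraction=study.noise_floor_fraction,
        seed=seed,
    )


#: loadings of (evaporation, trophic) onto each environmental covariate,
#: plus an affine scale/offset taking the standardized value to plausible
#: field units.  d-excess decreases with evaporation; TP is log-linear in
#: the trophic gradient.
_ENV_MODEL: dict[str, tuple[float, float, float, float]] = {
    # name: (loading_evap, loading_troph, scale, offset)
    "wind": (0.0, 0.0, 1.5, 4.0),
    "precipitation": (-0.6, 0.0, 25.0, 80.0),
    "pct_forestry": (0.0, -0.3, 12.0, 40.0),
    "pct_grassland": (0.2, 0.3, 8.0, 15.0),
    "pct_water": (-0.3, 0.0, 5.0, 8.0),
    "pct_natural": (-0.4, -0.4, 15.0, 60.0),
    "pct_mines": (0.0, 0.1, 1.0, 1.0),
    "watershed_area": (0.1, 0.0, 50.0, 120.0),
    "lake_area": (0.0, 0.0, 3.0, 5.0),
    "WRT": (0.7, 0.2, 2.0, 3.5),
    "Twater": (0.3, 0.4, 3.0, 18.0),
    "DIC": (0.2, 0.5, 4.0, 8.0),
    "S275_295": (0.4, 0.3, 0.004, 0.020),
    "d_excess": (-0.9, 0.0, 8.0, -5.0),
    "TN": (0.1, 0.7, 150.0, 400.0),
    "TP": (0.0, 0.9, 0.9, 2.8),  # log-scale: TP = exp(scale*z + offset)
    "DO": (-0.1, -0.4, 1.5, 8.5),
    "BA": (-0.2, -0.5, 1.2e6, 3.5e6),
}


@dataclass
class StudyData:
    clouds: list[EventCloud]
    env_table: pd.DataFrame  # indexed by sample id, ENV_COLUMNS
    truth: dict  # gradients per sample, per-sample cloud truths, env model


def generate_study(spec: StudySpec) -> StudyData:
    """Draw a full study: duplicated clouds, environmental table, truth."""
    rng = np.random.default_rng(spec.seed)
    sample_ids = [f"lake{i:03d}" for i in range(spec.n_samples)]
    evap = rng.standard_normal(spec.n_samples)
    troph = rng.standard_normal(spec.n_samples)

    env_rows = {}
    for name, (le, lt, scale, offset) in _ENV_MODEL.items():
        z = le * evap + lt * troph + spec.env_noise_sd * rng.standard_normal(
            spec.n_samples
        )
        if name == "TP":
            env_rows[name] = np.exp(scale * z + offset)
        else:
            env_rows[name] = scale * z + offset
    env = pd.DataFrame(env_rows, index=pd.Index(sample_ids, name="sample_id"))
    env = env[list(ENV_COLUMNS)]

    clouds: list[EventCloud] = []
    cloud_truths: dict[str, dict] = {}
    for i, sid in enumerate(sample_ids):
        base_seed = int(rng.integers(0, 2**31 - 1))
        cspec = _cloud_spec_for(evap[i], troph[i], spec, rng, seed=base_seed)
        for r in range(spec.n_replicates):
            rspec = CloudSpec(
                components=cspec.components,
                n_events=cspec.n_events,
                noise_floor_fraction=cspec.noise_floor_fraction,
                fl1_threshold=cspec.fl1_threshold,
                seed=base_seed + r,
            )
            cloud, truth = generate_cloud(rspec, sample_id=sid, replicate_id=f"r{r+1}")
            clouds.append(cloud)
            if r == 0:
                cloud_truths[sid] = truth

    truth = {
        "gradients": pd.DataFrame(
            {"evaporation": evap, "trophic": troph},
            index=pd.Index(sample_ids, name="sample_id"),
        ),
        "clouds": cloud_truths,
        "env_model": dict(_ENV_MODEL),
    }
    return StudyData(clouds=clouds, env_table=env, truth=truth)


def write_study(data: StudyData, outdir, fmt: str = "csv") -> pd.DataFrame:
    """Write event files, environmental table and truth tables; returns the
    manifest (sample_id, replicate_id, path)."""
    import pathlib

    outdir = pathlib.Path(outdir)
    (outdir / "events").mkdir(parents=True, exist_ok=True)
    rows = []
    for cloud in data.clouds:
        name = f"{cloud.sample_id}_{cloud.replicate_id}.{fmt}"
        path = outdir / "events" / name
        raw = pd.DataFrame(
            10.0**cloud.values, columns=["SSC-H", "FL1-H", "FSC-H"]
        )
        if fmt == "fcs":
            from ._fcs import write_minimal_fcs

            write_minimal_fcs(raw, path)
        else:
            raw.to_csv(path, index=False)
        rows.append(
            {
                "sample_id": cloud.sample_id,
                "replicate_id": cloud.replicate_id,
                "path": str(path),
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    data.env_table.to_csv(outdir / "environment.csv")
    data.truth["gradients"].to_csv(outdir / "truth_gradients.csv")
    return manifest
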