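"""Seeded synthetic cohorts with known injected effects.

The study's data are not publicly deposited, so validation runs on simulated
cohorts that emulate its design: two diagnostic groups (PTSD n=28, MDD n=24),
two resting scans per subject bracketing an affective stressor, parcellated
cortical timeseries with block-structured inter-node correlations organized by
six intrinsic connectivity networks, and subject-level covariates and symptom
scores.

Two generation modes:

* **timeseries** (`simulate_cohort`) draws each scan from a zero-mean
  multivariate normal whose correlation matrix is block-structured by network
  affiliation.  Subject-, scan- and condition-specific variation in the
  within-DMN correlation is injected additively in Fisher-z space and
  back-transformed, so injected decrements are exact on the analysis scale
  (which averages z, not r).  The group x stress interaction of size ``d`` is
  a z-decrement of ``d * sqrt(2) * scan_sd`` on PTSD post scans, making the
  standardized difference-score effect equal ``d`` up to the (small)
  attenuation from finite-frame strength estimation.
* **strength** (`simulate_strengths`) skips timeseries and draws pre/post
  network strengths directly from the normal model ``pre ~ N(mu, sigma_s^2)``,
  ``post = pre + shift_group + N(0, sigma_d^2)``, with the shift parameterized
  so the standardized interaction effect equals ``dmn_interaction_effect``
  exactly.  This is the fast path for power and type-I-error experiments.

Gaussian white timeseries (no autocorrelation) are the default so closed-form
expectations stay exact; an AR(1) option exists for realism checks.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .atlas_io import NETWORK_LABELS, NetworkAtlas, ParcelTimeseries, write_timeseries
from .connectome import scan_strength
from .inference import CohortTable

__all__ = ["SimConfig", "SimOutput", "simulate_cohort", "simulate_strengths",
           "make_default_atlas"]


def make_default_atlas(n_nodes: int = 60, dmn_fraction: float = 75 / 360) -> NetworkAtlas:
    """Deterministic partition of ``n_nodes`` into the six networks.

    The DMN receives ``round(dmn_fraction * n_nodes)`` members (at least 2);
    the remainder is split as evenly as possible over the other five
    networks.  The default fraction gives a 75-node DMN at the full 360-node
    parcellation.
    """
    if n_nodes < 12:
        raise ValueError("need n_nodes >= 12")
    if not (0.0 < dmn_fraction < 1.0):
        raise ValueError("dmn_fraction must lie in (0, 1)")
    n_dmn = max(2, int(round(dmn_fraction * n_nodes)))
    rest = n_nodes - n_dmn
    others = NETWORK_LABELS[1:]
    if rest < len(others):
        raise ValueError("dmn_fraction too large: other networks need >=1 node")
    base, extra = divmod(rest, len(others))
    sizes = {"DMN": n_dmn}
    for i, net in enumerate(others):
        sizes[net] = base + (1 if i < extra else 0)
    width = max(3, len(str(n_nodes)))
    node_ids, affiliation = [], {}
    i = 0
    for net in NETWORK_LABELS:
        for _ in range(sizes[net]):
            nid = f"p{i:0{width}d}"
            node_ids.append(nid)
            affiliation[nid] = net
            i += 1
    return NetworkAtlas(node_ids=tuple(node_ids), affiliation=affiliation)


@dataclass(frozen=True)
class SimConfig:
    """Generative configuration for one synthetic cohort.

    Defaults are a reduced scale (60 nodes, 200 frames, 10 + 10 subjects) for
    fast experimentation; ``SimConfig.study_scale()`` gives the full design
    (360 nodes, 645 retained frames, 28 + 24 subjects).

    Correlation parameters are on the Pearson scale; all injected effects act
    additively in Fisher-z space.  ``dmn_interaction_effect`` is the
    standardized (Cohen's d on the difference-score scale) within-DMN
    decrement for the PTSD group's post scan.  ``drift_effect`` maps group ->
    z-change of within-DMN correlation in the second half of each run.
    """

    n_ptsd: int = 10
    n_mdd: int = 10
    n_nodes: int = 60
    frames: int = 200
    tr_seconds: float = 0.7
    atlas: Optional[NetworkAtlas] = None
    dmn_fraction: float = 75 / 360
    rho_within: float | dict = 0.3
    rho_between: float = 0.05
    dmn_interaction_effect: float = 0.0
    group_effect: float = 0.0   # z-shift of within-DMN corr, PTSD, both scans
    stress_effect: float = 0.0  # z-shift of within-DMN corr, post, both groups
    drift_effect: dict = field(default_factory=lambda: {"PTSD": 0.0, "MDD": 0.0})
    subject_sd: float = 0.033   # between-subject SD of within-DMN z
    scan_sd: float = 0.08       # scan-to-scan SD of within-DMN z
    noise_sd: float = 0.0       # white observation noise added to the series
    ar1: float = 0.0            # optional AR(1) coefficient for the series
    nodal_effect_nodes: tuple = ()     # DMN node ids carrying a focal decrement
    nodal_effect_delta_z: float = 0.0  # z-decrement on pairs touching them
    # strength-mode parameters (scale of the NRS outcome)
    strength_mean: float = 0.13
    strength_subject_sd: float = 0.033
    strength_diff_sd: float = 0.026
    covariate_model: str = "default"  # "default" | "none"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ptsd < 2 or self.n_mdd < 2:
            raise ValueError("each group needs >=2 subjects")
        if self.frames < 6:
            raise ValueError("need >= 6 frames")
        if self.strength_subject_sd <= 0 or self.strength_diff_sd <= 0:
            raise ValueError("strength-mode SDs must be positive")
        if not (-1.0 < self.ar1 < 1.0):
            raise ValueError("ar1 must lie in (-1, 1)")
        if self.covariate_model not in ("default", "none"):
            raise ValueError("covariate_model must be 'default' or 'none'")

    def resolved_atlas(self) -> NetworkAtlas:
        if self.atlas is not None:
            return self.atlas
        return make_default_atlas(self.n_nodes, self.dmn_fraction)

    @classmethod
    def study_scale(cls, **overrides) -> "SimConfig":
        """The study's design: 28 + 24 subjects, 360 nodes, 645 frames."""
        base = dict(n_ptsd=28, n_mdd=24, n_nodes=360, frames=645)
        base.update(overrides)
        return cls(**base)

    def rho_for(self, network: str) -> float:
        if isinstance(self.rho_within, dict):
            return float(self.rho_within.get(network, 0.0))
        return float(self.rho_within)


@dataclass(frozen=True)
class SimOutput:
    """A generated cohort: timeseries (timeseries mode only), cohort table,
    atlas, and provenance metadata."""

    cohort: CohortTable
    atlas: Optional[NetworkAtlas]
    metadata: dict
    timeseries: Optional[dict] = None  # subject_id -> {"pre": ts, "post": ts}

    def write(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        from .atlas_io import write_atlas

        self.cohort.subjects.to_csv(out / "subjects.csv", index=False)
        strengths = []
        for _, row in self.cohort.subjects.iterrows():
            for scan, col in (("pre", "strength_pre"), ("post", "strength_post")):
                strengths.append(
                    {"subject": row["subject_id"], "scan_label": scan,
                     "network": "DMN", "value": row[col]}
                )
        pd.DataFrame(strengths).to_csv(out / "strengths.csv", index=False)
        if self.atlas is not None:
            write_atlas(self.atlas, out / "atlas.tsv")
        if self.timeseries is not None:
            ts_dir = out / "timeseries"
            ts_dir.mkdir(exist_ok=True)
            for sid, scans in self.timeseries.items():
                for scan, ts in scans.items():
                    write_timeseries(ts, ts_dir / f"{sid}_{scan}.tsv")
        (out / "metadata.json").write_text(json.dumps(self.metadata, indent=2,
                                                      sort_keys=True))
        return out


def _base_z_matrix(atlas: NetworkAtlas, rho_within, rho_between) -> np.ndarray:
    """Fisher-z block matrix from network affiliations (zero diagonal)."""
    nets = np.array([atlas.affiliation[n] for n in atlas.node_ids])
    n = len(nets)
    z = np.full((n, n), np.arctanh(float(rho_between)))
    for net in set(nets):
        rho = rho_within.get(net, 0.0) if isinstance(rho_within, dict) else rho_within
        m = nets == net
        z[np.ix_(m, m)] = np.arctanh(float(rho))
    np.fill_diagonal(z, 0.0)
    return z


def _checked_cholesky(corr: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        eig = float(np.linalg.eigvalsh(corr).min())
        raise ValueError(
            f"block correlation matrix is not positive definite "
            f"(minimum eigenvalue {eig:.3e}); reduce the injected shifts"
        ) from None


def _draw_frames(rng: np.random.Generator, chol: np.ndarray, frames: int,
                 ar1: float) -> np.ndarray:
    n = chol.shape[0]
    eps = rng.standard_normal((n, frames))
    if ar1 != 0.0:
        # innovations scaled so the stationary marginal variance stays 1
        out = np.empty_like(eps)
        out[:, 0] = eps[:, 0]
        scale = np.sqrt(1.0 - ar1 * ar1)
        for t in range(1, frames):
            out[:, t] = ar1 * out[:, t - 1] + scale * eps[:, t]
        eps = out
    return chol @ eps


def _covariates(rng: np.random.Generator, group: str) -> dict:
    """Demographics, motion, medication/comorbidity flags and symptom scores
    for one subject (distributions emulate the study's Table 1 margins)."""
    age = float(np.clip(rng.normal(41.4, 10.0), 21.0, 68.0))
    cov = {
        "age": age,
        "sex_male": int(rng.random() < 0.67),
        "motion_pre": float(np.exp(rng.normal(np.log(0.10), 0.3))),
        "motion_post": float(np.exp(rng.normal(np.log(0.095), 0.3))),
        "antidepressant": int(rng.random() < 0.46),
        "substance_use": int(rng.random() < 0.10),
        "alcohol_use": int(rng.random() < 0.13),
        "generalized_anxiety": int(rng.random() < 0.29),
        "panic": int(rng.random() < 0.21),
        "ocd": int(rng.random() < 0.04),
        "social_anxiety": int(rng.random() < 0.27),
    }
    if group == "PTSD":
        cov.update(
            QIDS=float(np.clip(rng.normal(13.43, 4.6), 0, 27)),
            PCL5_total=float(np.clip(rng.normal(38.0, 12.0), 0, 80)),
            caps_reexperiencing=float(np.clip(rng.normal(10.0, 4.0), 0, 20)),
            caps_avoidance=float(np.clip(rng.normal(4.0, 2.0), 0, 8)),
            caps_negative_mood=float(np.clip(rng.normal(14.0, 6.0), 0, 28)),
            caps_arousal=float(np.clip(rng.normal(12.0, 4.0), 0, 24)),
        )
    else:
        cov.update(QIDS=float(np.clip(rng.normal(12.17, 5.4), 0, 27)),
                   PCL5_total=np.nan, caps_reexperiencing=np.nan,
                   caps_avoidance=np.nan, caps_negative_mood=np.nan,
                   caps_arousal=np.nan)
    return cov


def _metadata(cfg: SimConfig, mode: str) -> dict:
    echo = dataclasses.asdict(cfg)
    echo["atlas"] = None if cfg.atlas is None else "custom"
    echo["nodal_effect_nodes"] = list(cfg.nodal_effect_nodes)
    return {"seed": cfg.seed, "mode": mode, "generator_version": __version__,
            "config": echo}


def simulate_cohort(
    cfg: SimConfig, keep_timeseries: bool = True, seed: int | None = None
) -> SimOutput:
    """Timeseries mode: per subject x scan multivariate-normal parcel series.

    Each scan is generated in two contiguous halves so a within-run drift can
    change the second half's within-DMN correlation; with zero drift the
    halves are identically distributed.  ``seed`` overrides ``cfg.seed``
    (convenient for replicate loops over one configuration).
    """
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    atlas = cfg.resolved_atlas()
    # validate positive-definiteness of the baseline block structure up front
    base_corr = np.tanh(_base_z_matrix(atlas, cfg.rho_within, cfg.rho_between))
    np.fill_diagonal(base_corr, 1.0)
    _checked_cholesky(base_corr)
    node_ids = atlas.node_ids
    nets = np.array([atlas.affiliation[n] for n in node_ids])
    dmn = nets == "DMN"
    base_z = _base_z_matrix(atlas, cfg.rho_within, cfg.rho_between)
    interaction_dz = -cfg.dmn_interaction_effect * np.sqrt(2.0) * cfg.scan_sd

    nodal_idx = np.array([i for i, n in enumerate(node_ids)
                          if n in set(cfg.nodal_effect_nodes)], dtype=int)
    if len(cfg.nodal_effect_nodes) != len(nodal_idx):
        missing = set(cfg.nodal_effect_nodes) - set(node_ids)
        raise ValueError(f"nodal_effect_nodes not in atlas: {sorted(missing)}")
    focal = np.zeros(len(node_ids), dtype=bool)
    focal[nodal_idx] = True
    touches_focal = (focal[:, None] | focal[None, :]) & dmn[:, None] & dmn[None, :]
    np.fill_diagonal(touches_focal, False)

    # Subject- and scan-level z jitter uses a bounded (uniform) distribution
    # scaled to the requested SD: the worst-case within-DMN z stays above the
    # block's positive-definiteness boundary (rho > -1/(m-1)) at the default
    # configuration, so the fail-loud PSD policy never trips by chance.
    def jitter(sd: float) -> float:
        return rng.uniform(-np.sqrt(3.0) * sd, np.sqrt(3.0) * sd)

    groups = ["PTSD"] * cfg.n_ptsd + ["MDD"] * cfg.n_mdd
    timeseries: dict = {}
    rows = []
    for s, group in enumerate(groups):
        sid = f"sub{s + 1:03d}"
        subj_dz = jitter(cfg.subject_sd)
        scans = {}
        for scan in ("pre", "post"):
            dz = subj_dz + jitter(cfg.scan_sd)
            if group == "PTSD":
                dz += -cfg.group_effect
            if scan == "post":
                dz += -cfg.stress_effect
                if group == "PTSD":
                    dz += interaction_dz
            drift = float(cfg.drift_effect.get(group, 0.0))
            halves = []
            n_h1 = cfg.frames - cfg.frames // 2
            for half, n_frames in (("h1", n_h1), ("h2", cfg.frames // 2)):
                z = base_z.copy()
                z[np.ix_(dmn, dmn)] += dz + (drift if half == "h2" else 0.0)
                if nodal_idx.size and group == "PTSD" and scan == "post":
                    z[touches_focal] -= cfg.nodal_effect_delta_z
                np.fill_diagonal(z, 0.0)
                corr = np.tanh(z)
                np.fill_diagonal(corr, 1.0)
                chol = _checked_cholesky(corr)
                halves.append(_draw_frames(rng, chol, n_frames, cfg.ar1))
            values = np.hstack(halves)
            if cfg.noise_sd > 0:
                values = values + rng.normal(0.0, cfg.noise_sd, values.shape)
            scans[scan] = ParcelTimeseries(values=values, node_ids=node_ids,
                                           tr_seconds=cfg.tr_seconds,
                                           scan_label=scan)
        row = {"subject_id": sid, "group": group,
               "strength_pre": scan_strength(scans["pre"], atlas, "DMN").value,
               "strength_post": scan_strength(scans["post"], atlas, "DMN").value}
        if cfg.covariate_model != "none":
            row.update(_covariates(rng, group))
        rows.append(row)
        if keep_timeseries:
            timeseries[sid] = scans
    cohort = CohortTable(subjects=pd.DataFrame(rows))
    meta = _metadata(cfg, "timeseries")
    meta["seed"] = seed
    return SimOutput(cohort=cohort, atlas=atlas, metadata=meta,
                     timeseries=timeseries if keep_timeseries else None)


def simulate_strengths(cfg: SimConfig, seed: int | None = None) -> SimOutput:
    """Strength mode: draw pre/post NRS values directly.

    ``post - pre`` has SD ``strength_diff_sd`` within each group and a
    PTSD-minus-MDD mean difference of ``-dmn_interaction_effect *
    strength_diff_sd``, so the standardized interaction effect equals the
    configured d exactly.
    """
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    groups = ["PTSD"] * cfg.n_ptsd + ["MDD"] * cfg.n_mdd
    rows = []
    for s, group in enumerate(groups):
        pre = cfg.strength_mean + rng.normal(0.0, cfg.strength_subject_sd)
        if group == "PTSD":
            pre += -cfg.group_effect * cfg.strength_subject_sd
        shift = -cfg.stress_effect * cfg.strength_diff_sd
        if group == "PTSD":
            shift += -cfg.dmn_interaction_effect * cfg.strength_diff_sd
        post = pre + shift + rng.normal(0.0, cfg.strength_diff_sd)
        row = {"subject_id": f"sub{s + 1:03d}", "group": group,
               "strength_pre": pre, "strength_post": post}
        if cfg.covariate_model != "none":
            row.update(_covariates(rng, group))
        rows.append(row)
    cohort = CohortTable(subjects=pd.DataFrame(rows))
    meta = _metadata(cfg, "strengths")
    meta["seed"] = seed
    return SimOutput(cohort=cohort, atlas=None, metadata=meta)
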