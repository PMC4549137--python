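"""Synthetic resting-state cohorts with known connectivity ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: two groups of subjects whose ROI signals are draws from
multivariate normal distributions with block-structured correlation
matrices; the patient matrix differs from the control matrix only at a
designated set of edges, shifted by signed correlation offsets
(hyper-/hypo-connectivity).  On top of the correlated latent signal each
region receives a baseline offset, a linear scanner drift, a shared
low-frequency physiological confound and white measurement noise; latent
signals are AR(1)-smoothed in time so frame-to-frame percent signal change
is realistically small.  Occasional frames carry a motion spike (a step
displacement in the motion trace plus a one-frame amplitude artifact in
all regions).  Clinical covariates of patients are linear functions of a
designated edge's measured connectivity plus noise, clipped to legal
ranges.

Defaults mirror the emulated study: 26 subjects per group, 116 regions,
120 volumes at TR = 2 s, and 19 perturbed edges at the positions of the
reported abnormal connections with |delta| = 0.3.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from .atlas import RegionAtlas, load_aal116
from .cohort import SubjectRecord, load_abnormal_connections
from .timeseries import MotionTrace, RoiTimeSeries

SARA_RANGE = (0.0, 40.0)


@dataclass(frozen=True)
class BehaviorCoupling:
    """Linear link between one edge's connectivity and one covariate."""

    edge: tuple[int, int]        # 0-based region positions, i < j
    covariate: str               # sara | years_of_symptoms | cag_expansion
    slope: float
    intercept: float
    noise_sd: float
    clip: tuple[float, float] = SARA_RANGE


@dataclass
class SimulationSpec:
    n_per_group: int = 26
    n_regions: int = 116
    n_volumes: int = 120
    tr: float = 2.0
    # control-group correlation profile: near-equal blocks
    n_blocks: int = 4
    within_block_r: float = 0.3
    between_block_r: float = 0.05
    block_sizes: Optional[list[int]] = None
    # group difference
    perturbed_edges: list[tuple[int, int, float]] = field(default_factory=list)
    # signal model (arbitrary units; baseline sets the percent-change scale)
    baseline: float = 1000.0
    signal_sd: float = 2.5
    noise_sd: float = 1.0
    ar_coef: float = 0.3
    drift_slope_sd: float = 0.02        # units per volume
    global_confound_amplitude: float = 1.5
    # motion model
    motion_spike_probability: float = 0.02
    motion_spike_magnitude_mm: float = 2.0
    artifact_amplitude: float = 10.0
    motion_jitter_sd: float = 0.0       # mm, continuous jitter (off by default)
    # behavior model
    behavior_couplings: list[BehaviorCoupling] = field(default_factory=list)
    region_names: Optional[list[str]] = None   # default: R001..R<n>
    seed: int = 0

    def resolved_block_sizes(self) -> list[int]:
        if self.block_sizes is not None:
            if sum(self.block_sizes) != self.n_regions:
                raise ValueError("block sizes must sum to the region count")
            return list(self.block_sizes)
        base, extra = divmod(self.n_regions, self.n_blocks)
        return [base + (1 if i < extra else 0) for i in range(self.n_blocks)]


def default_study_spec() -> tuple[SimulationSpec, RegionAtlas]:
    """Study-scale simulation: 26/26 subjects, 116 regions, 120 volumes,
    TR 2 s, 19 perturbed edges at the reported abnormal connections."""
    atlas = load_aal116()
    table = load_abnormal_connections()
    edges = []
    for _, row in table.iterrows():
        i = atlas.position(row["region_i"])
        j = atlas.position(row["region_j"])
        i, j = min(i, j), max(i, j)
        delta = 0.3 if row["direction"] == "increase" else -0.3
        edges.append((i, j, delta))
    # SARA and symptom duration decrease as the coupled edge's connectivity
    # rises (the edge is hyperconnected in patients)
    mf_l = atlas.position("Frontal_Mid_L")
    sf_r = atlas.position("Frontal_Sup_R")
    coupled = (min(mf_l, sf_r), max(mf_l, sf_r))
    # intercepts place the covariates in plausible clinical ranges given the
    # raw-series connectivity the coupled edge actually exhibits (~0.64)
    couplings = [
        BehaviorCoupling(coupled, "sara", slope=-40.0, intercept=40.0,
                         noise_sd=3.0),
        BehaviorCoupling(coupled, "years_of_symptoms", slope=-30.0,
                         intercept=28.0, noise_sd=3.0, clip=(0.5, 40.0)),
    ]
    return SimulationSpec(perturbed_edges=edges,
                          behavior_couplings=couplings,
                          region_names=atlas.names), atlas


def small_test_spec(**overrides) -> SimulationSpec:
    """A fast 20-region profile sharing the study's n, T and TR."""
    spec = SimulationSpec(n_regions=20, n_blocks=2,
                          perturbed_edges=[(0, 5, 0.3), (2, 12, -0.3),
                                           (7, 15, 0.35)])
    for k, v in overrides.items():
        setattr(spec, k, v)
    return spec


# --------------------------------------------------------------------------
# correlation targets

def block_correlation(block_sizes: Sequence[int], within: float,
                      between: float) -> np.ndarray:
    """Block-constant correlation matrix with unit diagonal."""
    R = sum(block_sizes)
    m = np.full((R, R), between)
    pos = 0
    for size in block_sizes:
        m[pos:pos + size, pos:pos + size] = within
        pos += size
    np.fill_diagonal(m, 1.0)
    return m


def apply_deltas(target: np.ndarray,
                 edges: Sequence[tuple[int, int, float]]) -> np.ndarray:
    """Shift designated edges by signed offsets (no PSD repair)."""
    out = target.copy()
    for i, j, delta in edges:
        if i == j:
            raise ValueError("perturbed edge must join two distinct regions")
        new = out[i, j] + delta
        if abs(new) >= 1:
            raise ValueError(
                f"delta {delta:+g} pushes edge ({i},{j}) to |r|={abs(new):g} >= 1")
        out[i, j] = out[j, i] = new
    return out


def nearest_correlation(a: np.ndarray, floor: float = 1e-6,
                        max_iter: int = 200, tol: float = 1e-10) -> np.ndarray:
    """Nearest correlation matrix by alternating projections (Higham 2002).

    Projects onto the positive-semidefinite cone (eigenvalues clipped to
    ``floor``) and onto the unit-diagonal affine set, with Dykstra's
    correction, until the iterates stabilize.
    """
    y = np.asarray(a, dtype=float)
    y = 0.5 * (y + y.T)
    ds = np.zeros_like(y)
    prev = y.copy()
    for _ in range(max_iter):
        r = y - ds
        vals, vecs = np.linalg.eigh(r)
        x = (vecs * np.maximum(vals, floor)) @ vecs.T
        x = 0.5 * (x + x.T)
        ds = x - r
        y = x.copy()
        np.fill_diagonal(y, 1.0)
        if np.max(np.abs(y - prev)) < tol:
            break
        prev = y.copy()
    else:
        raise RuntimeError("nearest-correlation repair did not converge")
    vals = np.linalg.eigvalsh(y)
    if vals.min() < -1e-8:
        raise RuntimeError("nearest-correlation repair left negative eigenvalues")
    return np.clip(y, -1.0, 1.0)


def make_group_targets(spec: SimulationSpec) -> tuple[np.ndarray, np.ndarray]:
    """Control and patient target correlation matrices.

    The patient matrix equals the control matrix except at the perturbed
    edges; both are repaired to valid (symmetric, PSD, unit-diagonal)
    correlation matrices when the edits break positive semidefiniteness.
    """
    control = block_correlation(spec.resolved_block_sizes(),
                                spec.within_block_r, spec.between_block_r)
    if np.linalg.eigvalsh(control).min() < 0:
        control = nearest_correlation(control)
    if not spec.perturbed_edges:
        return control, control.copy()
    patient = apply_deltas(control, spec.perturbed_edges)
    if np.linalg.eigvalsh(patient).min() < 0:
        patient = nearest_correlation(patient)
    return control, patient


# --------------------------------------------------------------------------
# subject-level simulation

def subject_rng(master_seed: int, subject_index: int) -> np.random.Generator:
    """Counter-based per-subject stream: independent of generation order."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=master_seed,
                               spawn_key=(subject_index,)))


def simulate_subject(target: np.ndarray, spec: SimulationSpec,
                     rng: np.random.Generator
                     ) -> tuple[RoiTimeSeries, MotionTrace]:
    """One subject's ROI time series and motion trace.

    The latent signal is a multivariate normal draw with the target
    correlation, AR(1)-smoothed in time (which preserves the cross-regional
    correlation structure).
    """
    vals = np.linalg.eigvalsh(target)
    if vals.min() < -1e-8:
        raise ValueError("target correlation matrix is not PSD")
    T, R = spec.n_volumes, target.shape[0]
    chol = np.linalg.cholesky(target + 1e-10 * np.eye(R))
    white = rng.standard_normal((T, R))
    latent = white @ chol.T
    rho = spec.ar_coef
    if rho:
        smoothed = np.empty_like(latent)
        smoothed[0] = latent[0]
        scale = np.sqrt(1.0 - rho ** 2)
        for t in range(1, T):
            smoothed[t] = rho * smoothed[t - 1] + scale * latent[t]
        latent = smoothed

    t_axis = np.arange(T, dtype=float)
    slopes = rng.normal(0.0, spec.drift_slope_sd, size=R)
    drift = np.outer(t_axis - t_axis.mean(), slopes)

    conf_freq = rng.uniform(0.01, 0.03)            # Hz, inside the pass band
    conf_phase = rng.uniform(0, 2 * np.pi)
    confound = spec.global_confound_amplitude * np.sin(
        2 * np.pi * conf_freq * t_axis * spec.tr + conf_phase)

    data = (spec.baseline
            + spec.signal_sd * latent
            + drift
            + confound[:, None]
            + spec.noise_sd * rng.standard_normal((T, R)))

    params = np.zeros((T, 6))
    if spec.motion_jitter_sd:
        params += rng.normal(0.0, spec.motion_jitter_sd, size=(T, 6))
    spikes = rng.random(T) < spec.motion_spike_probability
    spikes[0] = False
    for t in np.flatnonzero(spikes):
        # step displacement: the head moves and stays, so FD flags one frame
        params[t:, 0] += spec.motion_spike_magnitude_mm * rng.choice([-1, 1])
        data[t] += spec.artifact_amplitude * rng.choice([-1, 1])

    names = spec.region_names or [f"R{i+1:03d}" for i in range(R)]
    if len(names) != R:
        raise ValueError("region_names length does not match the target size")
    return (RoiTimeSeries(data, spec.tr, list(names)), MotionTrace(params))


# --------------------------------------------------------------------------
# behavior

def edge_value(ts: RoiTimeSeries, edge: tuple[int, int]) -> float:
    """Sample Pearson correlation of one region pair on the raw series."""
    i, j = edge
    return float(np.corrcoef(ts.data[:, i], ts.data[:, j])[0, 1])


def simulate_behavior(records: Sequence[SubjectRecord],
                      edge_values: dict[str, float],
                      coupling: BehaviorCoupling,
                      rng: np.random.Generator) -> list[SubjectRecord]:
    """Fill one covariate of each patient from the coupled edge's value."""
    out = []
    for rec in records:
        if rec.group != "patient":
            out.append(rec)
            continue
        if rec.id not in edge_values:
            raise ValueError(f"no edge value for patient {rec.id!r}")
        value = (coupling.intercept
                 + coupling.slope * edge_values[rec.id]
                 + rng.normal(0.0, coupling.noise_sd))
        value = float(np.clip(value, *coupling.clip))
        fields = {**asdict(rec), coupling.covariate: value}
        if coupling.covariate == "cag_expansion":
            fields["cag_expansion"] = int(round(value))
        out.append(SubjectRecord(**fields))
    return out


# --------------------------------------------------------------------------
# cohort assembly

@dataclass
class SyntheticCohort:
    spec: SimulationSpec
    records: list[SubjectRecord]
    series: dict[str, RoiTimeSeries]
    motion: dict[str, MotionTrace]
    control_target: np.ndarray
    patient_target: np.ndarray

    @property
    def labels(self) -> np.ndarray:
        """+1 for patients, -1 for controls, in record order."""
        return np.array([1 if r.group == "patient" else -1
                         for r in self.records])


def generate_cohort(spec: SimulationSpec, master_seed: int | None = None
                    ) -> SyntheticCohort:
    """Draw a full two-group cohort.

    Subject seeds derive from (master seed, subject index) so each
    subject's data are reproducible independent of generation order.
    Patient covariates needing no coupling are drawn from plausible
    clinical ranges; coupled covariates follow the spec's linear links to
    the measured connectivity of the designated edge.
    """
    if master_seed is None:
        master_seed = spec.seed
    control_t, patient_t = make_group_targets(spec)
    meta_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=master_seed, spawn_key=(10 ** 6,)))

    records: list[SubjectRecord] = []
    series: dict[str, RoiTimeSeries] = {}
    motion: dict[str, MotionTrace] = {}
    n = spec.n_per_group
    patient_ages = meta_rng.integers(18, 69, size=n)
    genders = meta_rng.permutation(
        ["F"] * round(n * 11 / 26) + ["M"] * (n - round(n * 11 / 26)))
    for g, (group, target) in enumerate(
            [("patient", patient_t), ("control", control_t)]):
        for s in range(n):
            idx = g * n + s
            sid = f"{'P' if group == 'patient' else 'C'}{s+1:02d}"
            rng = subject_rng(master_seed, idx)
            ts, m = simulate_subject(target, spec, rng)
            series[sid], motion[sid] = ts, m
            age = int(patient_ages[s])
            if group == "control":
                age = int(np.clip(age + meta_rng.integers(-2, 3), 18, 90))
            rec = SubjectRecord(
                id=sid, group=group, age=age, gender=str(genders[s]),
                years_of_symptoms=float(meta_rng.integers(1, 24))
                if group == "patient" else None,
                cag_expansion=int(meta_rng.integers(41, 62))
                if group == "patient" else None,
                sara=float(meta_rng.uniform(4, 30)) if group == "patient"
                else None,
            )
            records.append(rec)

    for coupling in spec.behavior_couplings:
        values = {r.id: edge_value(series[r.id], coupling.edge)
                  for r in records if r.group == "patient"}
        records = simulate_behavior(records, values, coupling, meta_rng)

    return SyntheticCohort(spec=spec, records=records, series=series,
                           motion=motion, control_target=control_t,
                           patient_target=patient_t)


def write_cohort(cohort: SyntheticCohort, outdir) -> None:
    """Write a cohort directory in the package's tabular formats."""
    from pathlib import Path

    from .cohort import write_subject_table

    outdir = Path(outdir)
    (outdir / "timeseries").mkdir(parents=True, exist_ok=True)
    (outdir / "motion").mkdir(parents=True, exist_ok=True)
    write_subject_table(cohort.records, outdir / "subjects.tsv")
    for sid, ts in cohort.series.items():
        ts.to_tsv(outdir / "timeseries" / f"{sid}.tsv")
    for sid, m in cohort.motion.items():
        m.to_tsv(outdir / "motion" / f"{sid}.tsv")
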