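"""Synthetic 8-lead median-beat ECG generator with planted class features.

A median beat is modelled as a sum of Gaussian bumps (P, Q, R, S, T waves),
one amplitude per lead (I, II, V1-V6), on a 1.2 s window sampled at 500 Hz.
Each of the nine diagnostic classes is planted as a morphological deviation
from the sinus-rhythm baseline:

* first-degree AV block  - P-to-R spacing (PR proxy) forced to 240 ms,
* atrial fibrillation    - P wave removed,
* sinus brady/tachycardia - T-P spacing stretched/compressed (rate proxy on a
  single beat, which carries no rhythm strip),
* right/left bundle branch block - QRS widened beyond 120 ms with opposite
  V1 polarity distinguishing right from left,
* low QRS voltage        - QRS amplitudes scaled below 0.5 mV,
* left ventricular hypertrophy - QRS amplitudes scaled up.

Records are grouped by patient: per-patient latent offsets (amplitude scale,
timing shift, width scale) are drawn once per patient and shared by all of
that patient's records, inducing within-patient correlation. Every record
carries a ground-truth relevance mask marking where its class modifiers
changed the noiseless signal relative to the baseline beat, which downstream
experiments use as a planted-feature oracle.

Labels can co-occur only when compatible (e.g. sinus rhythm + AV block, never
sinus rhythm + atrial fibrillation); sampling is hierarchical so that every
class marginal equals its configured prevalence exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, SplitError

LEADS = ("I", "II", "V1", "V2", "V3", "V4", "V5", "V6")
WAVES = ("P", "Q", "R", "S", "T")

SINUS_RHYTHM = "sinus_rhythm"
ATRIAL_FIBRILLATION = "atrial_fibrillation"
SINUS_BRADYCARDIA = "sinus_bradycardia"
SINUS_TACHYCARDIA = "sinus_tachycardia"
AV_BLOCK = "first_degree_av_block"
RBBB = "right_bundle_branch_block"
LBBB = "left_bundle_branch_block"
LOW_QRS_VOLTAGE = "low_qrs_voltage"
LVH = "left_ventricular_hypertrophy"

CLASSES = (SINUS_RHYTHM, ATRIAL_FIBRILLATION, SINUS_BRADYCARDIA, SINUS_TACHYCARDIA,
           AV_BLOCK, RBBB, LBBB, LOW_QRS_VOLTAGE, LVH)

#: emulated composition (training-set fractions of the archive the study drew on)
DEFAULT_PREVALENCES = {
    SINUS_RHYTHM: 0.629, ATRIAL_FIBRILLATION: 0.062, SINUS_BRADYCARDIA: 0.108,
    SINUS_TACHYCARDIA: 0.072, AV_BLOCK: 0.061, RBBB: 0.083, LBBB: 0.042,
    LOW_QRS_VOLTAGE: 0.036, LVH: 0.071,
}

MASK_THRESHOLD_MV = 0.01  # |noiseless class - baseline| above this marks relevance

#: internal morphology for records whose rhythm is none of the four named
#: classes (an ectopic-atrial proxy: inverted P wave). Without it those
#: records would be morphologically identical to sinus rhythm while carrying
#: a negative sinus-rhythm label, making that class unlearnable.
ECTOPIC_ATRIAL = "_ectopic_atrial"


@dataclass
class WaveComponent:
    """One Gaussian bump: per-lead amplitude (mV), center (s), width (s, SD)."""

    wave_id: str
    amplitude: np.ndarray  # [8]
    center: float
    width: float

    def __post_init__(self):
        self.amplitude = np.asarray(self.amplitude, float)
        if self.width <= 0:
            raise ConfigurationError(f"wave {self.wave_id}: width must be > 0")


@dataclass
class BeatParams:
    """A full beat: the five waves keyed by wave id."""

    waves: dict

    def copy(self) -> "BeatParams":
        return BeatParams({k: WaveComponent(w.wave_id, w.amplitude.copy(), w.center, w.width)
                           for k, w in self.waves.items()})

    @property
    def pr_interval(self) -> float:
        """P-peak to R-peak spacing (seconds), the PR-interval proxy."""
        return self.waves["R"].center - self.waves["P"].center

    @property
    def qrs_duration(self) -> float:
        """Q onset to S offset (2 SD beyond the peaks), seconds."""
        q, s = self.waves["Q"], self.waves["S"]
        return (s.center + 2 * s.width) - (q.center - 2 * q.width)


def default_baseline(record_duration_s: float = 1.2) -> BeatParams:
    """Sinus-rhythm median beat centred in the record window."""
    r = record_duration_s / 2.0  # R peak at window centre
    amp = {
        "P": [0.08, 0.12, 0.05, 0.06, 0.07, 0.07, 0.06, 0.05],
        "Q": [-0.08, -0.10, 0.00, 0.00, -0.02, -0.05, -0.08, -0.10],
        "R": [0.70, 1.10, 0.30, 0.60, 0.90, 1.40, 1.30, 1.00],
        "S": [-0.20, -0.25, -0.90, -0.80, -0.50, -0.30, -0.20, -0.15],
        "T": [0.25, 0.30, 0.10, 0.35, 0.40, 0.38, 0.32, 0.28],
    }
    center = {"P": r - 0.16, "Q": r - 0.030, "R": r, "S": r + 0.035, "T": r + 0.30}
    width = {"P": 0.020, "Q": 0.008, "R": 0.012, "S": 0.010, "T": 0.060}
    return BeatParams({w: WaveComponent(w, amp[w], center[w], width[w]) for w in WAVES})


@dataclass(frozen=True)
class ClassSpec:
    """A diagnostic class as a transformation of the baseline beat."""

    label: str
    modify: object = None  # callable BeatParams -> BeatParams (None = baseline)

    def apply(self, params: BeatParams) -> BeatParams:
        return params if self.modify is None else self.modify(params.copy())


def _scale_qrs(params: BeatParams, factor: float) -> BeatParams:
    for w in ("Q", "R", "S"):
        params.waves[w].amplitude *= factor
    return params


def _widen_qrs(params: BeatParams) -> BeatParams:
    for w in ("Q", "R", "S"):
        params.waves[w].width *= 2.2
    params.waves["Q"].center -= 0.015
    params.waves["S"].center += 0.030
    return params


def make_class_specs(baseline: BeatParams | None = None) -> dict:
    """The nine class specs, keyed by class name.

    Raises ConfigurationError if the baseline lacks a required wave.
    """
    baseline = baseline if baseline is not None else default_baseline()
    missing = [w for w in WAVES if w not in baseline.waves]
    if missing:
        raise ConfigurationError(f"baseline beat is missing wave components: {missing}")

    def af(p):
        p.waves["P"].amplitude[...] = 0.0
        return p

    def avb(p):
        p.waves["P"].center = p.waves["R"].center - 0.24  # PR proxy 240 ms > 200 ms
        return p

    def brady(p):
        # slow rate widens the T-to-next-P gap: T drifts late and broadens.
        # The P (and hence PR) is untouched so rate does not confound AV block.
        p.waves["T"].center += 0.08
        p.waves["T"].width *= 1.15
        return p

    def tachy(p):
        p.waves["T"].center -= 0.07
        p.waves["T"].width *= 0.90
        return p

    def rbbb(p):
        _widen_qrs(p)
        p.waves["R"].amplitude[2] = 0.85   # tall secondary R in V1
        p.waves["S"].amplitude[2] = -0.20
        p.waves["S"].amplitude[7] = -0.60  # slurred lateral S
        return p

    def lbbb(p):
        _widen_qrs(p)
        p.waves["R"].amplitude[2] = 0.05   # V1 dominantly negative
        p.waves["S"].amplitude[2] = -1.30
        p.waves["R"].amplitude[7] = 1.35
        p.waves["Q"].amplitude[7] = 0.0
        return p

    return {
        SINUS_RHYTHM: ClassSpec(SINUS_RHYTHM, None),
        ATRIAL_FIBRILLATION: ClassSpec(ATRIAL_FIBRILLATION, af),
        SINUS_BRADYCARDIA: ClassSpec(SINUS_BRADYCARDIA, brady),
        SINUS_TACHYCARDIA: ClassSpec(SINUS_TACHYCARDIA, tachy),
        AV_BLOCK: ClassSpec(AV_BLOCK, avb),
        RBBB: ClassSpec(RBBB, rbbb),
        LBBB: ClassSpec(LBBB, lbbb),
        LOW_QRS_VOLTAGE: ClassSpec(LOW_QRS_VOLTAGE, lambda p: _scale_qrs(p, 0.30)),
        LVH: ClassSpec(LVH, lambda p: _scale_qrs(p, 1.80)),
    }


@dataclass
class PatientLatent:
    """Per-patient offsets shared by all of a patient's records."""

    amp_scale: dict   # wave -> multiplicative factor
    center_shift: dict  # wave -> additive seconds
    width_scale: float

    def apply(self, params: BeatParams) -> BeatParams:
        out = params.copy()
        for w, wave in out.waves.items():
            wave.amplitude *= self.amp_scale.get(w, 1.0)
            wave.center += self.center_shift.get(w, 0.0)
            wave.width *= self.width_scale
        return out


def draw_patient_latent(rng: np.random.Generator, amp_sd=0.08, time_sd=0.004,
                        width_sd=0.05) -> PatientLatent:
    return PatientLatent(
        amp_scale={w: float(rng.normal(1.0, amp_sd)) for w in WAVES},
        center_shift={w: float(rng.normal(0.0, time_sd)) for w in WAVES},
        width_scale=float(abs(rng.normal(1.0, width_sd))),
    )


IDENTITY_LATENT = PatientLatent({}, {}, 1.0)


@dataclass
class ECGRecord:
    patient_id: str
    record_id: str
    signal: np.ndarray          # [8, L] mV
    sampling_rate: float
    labels: np.ndarray          # [9] binary over CLASSES
    relevance_mask: np.ndarray | None = None  # [8, L] bool

    def __post_init__(self):
        self.signal = np.asarray(self.signal, float)
        if self.signal.ndim != 2 or self.signal.shape[0] != 8:
            raise ValueError("signal must be [8 leads x L samples]")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite values")
        if self.relevance_mask is not None and self.relevance_mask.shape != self.signal.shape:
            raise ValueError("relevance mask shape must match signal")


def render_beat(params: BeatParams, n_samples: int, sampling_rate: float) -> np.ndarray:
    """Noiseless sum-of-Gaussians signal, [8, L] mV."""
    t = np.arange(n_samples) / sampling_rate
    sig = np.zeros((8, n_samples))
    for wave in params.waves.values():
        bump = np.exp(-((t - wave.center) ** 2) / (2.0 * wave.width ** 2))
        sig += wave.amplitude[:, None] * bump[None, :]
    return sig


def _mask_from_specs(specs, latent, n_samples, sampling_rate, baseline) -> np.ndarray:
    """Relevance = where the class modifiers changed the noiseless signal.

    Pure sinus-rhythm beats get the P-wave window (the feature whose normal
    presence distinguishes them from the rhythm classes).
    """
    base_params = latent.apply(baseline)
    params = base_params
    non_baseline = [s for s in specs if s.modify is not None]
    for s in non_baseline:
        params = s.apply(params)
    if not non_baseline:
        if any(s.label == SINUS_RHYTHM for s in specs):
            p = base_params.waves["P"]
            t = np.arange(n_samples) / sampling_rate
            window = np.abs(t - p.center) <= 3 * p.width
            return np.repeat(window[None, :], 8, axis=0)
        return np.zeros((8, n_samples), bool)
    diff = render_beat(params, n_samples, sampling_rate) - render_beat(
        base_params, n_samples, sampling_rate)
    return np.abs(diff) > MASK_THRESHOLD_MV


def class_discriminative_region(class_name: str, record_duration_s: float = 1.2,
                                sampling_rate: float = 500.0,
                                baseline: BeatParams | None = None) -> np.ndarray:
    """[8, L] bool: where the class modifier changes the nominal baseline beat.

    This is the class-level planted-feature region (identity patient latent),
    used as the ground-truth "oracle" ranking region when scoring how well
    attribution methods locate the feature that defines a classification task.
    """
    baseline = baseline if baseline is not None else default_baseline(record_duration_s)
    n = int(round(record_duration_s * sampling_rate))
    spec = make_class_specs(baseline)[class_name]
    return _mask_from_specs([spec], IDENTITY_LATENT, n, sampling_rate, baseline)


def sample_record(spec, patient_latent: PatientLatent = IDENTITY_LATENT,
                  noise_sd: float = 0.0, rng_seed: int = 0, *,
                  record_duration_s: float = 1.2, sampling_rate: float = 500.0,
                  baseline: BeatParams | None = None,
                  patient_id: str = "p0", record_id: str = "r0") -> ECGRecord:
    """Render one labelled record; bit-identical for identical arguments.

    ``spec`` may be a single ClassSpec or a sequence (compatible co-labels,
    applied in order).
    """
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be >= 0")
    specs = [spec] if isinstance(spec, ClassSpec) else list(spec)
    baseline = baseline if baseline is not None else default_baseline(record_duration_s)
    n = int(round(record_duration_s * sampling_rate))
    params = patient_latent.apply(baseline)
    for s in specs:
        params = s.apply(params)
    sig = render_beat(params, n, sampling_rate)
    if noise_sd > 0:
        sig = sig + np.random.default_rng(rng_seed).normal(0.0, noise_sd, sig.shape)
    labels = np.array([int(any(s.label == c for s in specs)) for c in CLASSES])
    mask = _mask_from_specs(specs, patient_latent, n, sampling_rate, baseline)
    return ECGRecord(patient_id, record_id, sig, sampling_rate, labels, mask)


@dataclass
class SyntheticDataset:
    records: list
    class_prevalences: np.ndarray
    generator_seed: int
    sampling_rate: float = 500.0
    classes: tuple = CLASSES

    @property
    def patient_index(self) -> dict:
        idx = {}
        for r in self.records:
            idx.setdefault(r.patient_id, []).append(r.record_id)
        return idx

    def __len__(self):
        return len(self.records)

    def signals(self) -> np.ndarray:
        return np.stack([r.signal for r in self.records])

    def labels_matrix(self) -> np.ndarray:
        return np.stack([r.labels for r in self.records])

    def labels_for(self, class_name: str) -> np.ndarray:
        return self.labels_matrix()[:, CLASSES.index(class_name)]

    def masks(self) -> np.ndarray:
        return np.stack([r.relevance_mask for r in self.records])

    def subset_by_patients(self, patient_ids) -> "SyntheticDataset":
        keep = set(patient_ids)
        return SyntheticDataset([r for r in self.records if r.patient_id in keep],
                                self.class_prevalences, self.generator_seed,
                                self.sampling_rate, self.classes)

    # -- on-disk container: float32 array + CSV manifest -------------------
    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        np.save(d / "signals.npy", self.signals().astype(np.float32))
        np.save(d / "masks.npy", self.masks().astype(bool))
        rows = []
        for r in self.records:
            row = {"patient_id": r.patient_id, "record_id": r.record_id}
            row.update({c: int(v) for c, v in zip(self.classes, r.labels)})
            rows.append(row)
        pd.DataFrame(rows).to_csv(d / "manifest.csv", index=False)
        meta = {"sampling_rate": self.sampling_rate, "generator_seed": int(self.generator_seed),
                "classes": list(self.classes),
                "class_prevalences": np.asarray(self.class_prevalences).tolist()}
        (d / "meta.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, directory) -> "SyntheticDataset":
        d = Path(directory)
        sig = np.load(d / "signals.npy").astype(float)
        masks = np.load(d / "masks.npy") if (d / "masks.npy").exists() else None
        manifest = pd.read_csv(d / "manifest.csv")
        meta = json.loads((d / "meta.json").read_text())
        classes = tuple(meta["classes"])
        records = []
        for i, row in manifest.iterrows():
            records.append(ECGRecord(
                str(row["patient_id"]), str(row["record_id"]), sig[i],
                meta["sampling_rate"], np.array([int(row[c]) for c in classes]),
                masks[i] if masks is not None else None))
        return cls(records, np.asarray(meta["class_prevalences"]),
                   meta["generator_seed"], meta["sampling_rate"], classes)


def _sample_labels(rng: np.random.Generator, prev: dict) -> list:
    """Hierarchical label draw with exact per-class marginals.

    Rhythm (sinus / AF / brady / tachy / unspecified) is categorical; the
    AV-block Bernoulli rate is rescaled by 1/P(P wave present) so its overall
    marginal matches the configured prevalence; bundle-branch morphology and
    voltage are categorical with an explicit "neither" outcome.
    """
    p_rhythm = [prev[SINUS_RHYTHM], prev[ATRIAL_FIBRILLATION],
                prev[SINUS_BRADYCARDIA], prev[SINUS_TACHYCARDIA]]
    rest = 1.0 - sum(p_rhythm)
    if rest < -1e-9:
        raise ConfigurationError("rhythm-class prevalences sum to more than 1")
    rhythm = rng.choice(5, p=p_rhythm + [max(rest, 0.0)])
    labels = []
    if rhythm == 0:
        labels.append(SINUS_RHYTHM)
    elif rhythm == 1:
        labels.append(ATRIAL_FIBRILLATION)
    elif rhythm == 2:
        labels.append(SINUS_BRADYCARDIA)
    elif rhythm == 3:
        labels.append(SINUS_TACHYCARDIA)
    p_has_p = 1.0 - prev[ATRIAL_FIBRILLATION]
    if rhythm != 1 and prev[AV_BLOCK] > 0:
        if rng.random() < min(prev[AV_BLOCK] / p_has_p, 1.0):
            labels.append(AV_BLOCK)
    u = rng.random()
    if u < prev[RBBB]:
        labels.append(RBBB)
    elif u < prev[RBBB] + prev[LBBB]:
        labels.append(LBBB)
    v = rng.random()
    if v < prev[LOW_QRS_VOLTAGE]:
        labels.append(LOW_QRS_VOLTAGE)
    elif v < prev[LOW_QRS_VOLTAGE] + prev[LVH]:
        labels.append(LVH)
    return labels


def generate_dataset(n_patients: int, mean_records_per_patient: float = 4.5,
                     prevalences: dict | None = None, noise_sd: float = 0.03,
                     seed: int = 0, *, record_duration_s: float = 1.2,
                     sampling_rate: float = 500.0,
                     latent_amp_sd: float = 0.08, latent_time_sd: float = 0.004,
                     latent_width_sd: float = 0.05) -> SyntheticDataset:
    """Patient-grouped labelled dataset; a pure function of (config, seed).

    Records per patient follow 1 + Poisson(mean - 1), strictly positive with
    the stated mean.
    """
    if n_patients < 1:
        raise ConfigurationError("n_patients must be >= 1")
    if mean_records_per_patient < 1:
        raise ConfigurationError("mean_records_per_patient must be >= 1")
    prev = dict(DEFAULT_PREVALENCES if prevalences is None else prevalences)
    missing = [c for c in CLASSES if c not in prev]
    if missing:
        raise ConfigurationError(f"prevalences missing classes: {missing}")
    vals = np.array([prev[c] for c in CLASSES], float)
    if np.any((vals < 0) | (vals > 1)):
        raise ConfigurationError("prevalences must lie in [0, 1]")
    if np.all(vals == 0):
        raise ConfigurationError("all-zero prevalences")

    baseline = default_baseline(record_duration_s)
    specs = make_class_specs(baseline)
    rng = np.random.default_rng(seed)
    records = []
    rec_counter = 0
    for pi in range(n_patients):
        pid = f"p{pi:05d}"
        latent = draw_patient_latent(rng, latent_amp_sd, latent_time_sd, latent_width_sd)
        n_rec = 1 + rng.poisson(mean_records_per_patient - 1.0)
        for _ in range(n_rec):
            labels = _sample_labels(rng, prev)
            active = [specs[c] for c in CLASSES if c in labels]
            rhythm_named = {SINUS_RHYTHM, ATRIAL_FIBRILLATION, SINUS_BRADYCARDIA,
                            SINUS_TACHYCARDIA}
            if not (rhythm_named & set(labels)):
                def _ectopic(p):
                    p.waves["P"].amplitude *= -1.0
                    return p
                active = [ClassSpec(ECTOPIC_ATRIAL, _ectopic)] + active
            rec = sample_record(
                active, latent, noise_sd, rng_seed=int(rng.integers(2 ** 31)),
                record_duration_s=record_duration_s, sampling_rate=sampling_rate,
                baseline=baseline, patient_id=pid, record_id=f"r{rec_counter:07d}")
            rec_counter += 1
            records.append(rec)
    return SyntheticDataset(records, vals, int(seed), sampling_rate)


def split_by_patient(ds: SyntheticDataset, n_val_patients: int, n_test_patients: int,
                     seed: int = 0):
    """Disjoint patient-level (train, validation, test) split, seed-reproducible."""
    patients = sorted(ds.patient_index)
    if n_val_patients + n_test_patients >= len(patients):
        raise SplitError(
            f"cannot reserve {n_val_patients}+{n_test_patients} patients out of {len(patients)}")
    perm = np.random.default_rng(seed).permutation(len(patients))
    val = {patients[i] for i in perm[:n_val_patients]}
    test = {patients[i] for i in perm[n_val_patients:n_val_patients + n_test_patients]}
    train = set(patients) - val - test
    return (ds.subset_by_patients(train), ds.subset_by_patients(val),
            ds.subset_by_patients(test))
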