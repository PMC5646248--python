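"""Synthetic dietary-crossover cohorts with planted, recoverable structure.

Emulates the data model of a resistant-starch crossover study: every subject
contributes one fecal sample per diet (baseline washout, low-RS, high-RS),
and each sample is measured on three layers — 16S OTU counts, metaproteome
spectral counts, and metabolite intensities.  The generator plants known
effects (dose-linear responses, diet shifts, cross-layer correlated modules)
so that every downstream stage has a ground truth to recover.

Count layers use a negative-binomial model with per-subject log-normal
random intercepts, matching the overdispersion and strong interpersonal
variation of real 16S and spectral-count data.  Spectral-count run totals
are deliberately unequal across runs, which is what the normalization stage
corrects.  Metabolite intensities are log-normal with missing-at-random
zeros (the aligned-matrix convention: absent peaks are stored as zero and
recoded as missing at the network stage).

All randomness flows from a single seed through one generator object.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .tables import (
    RS_DOSE,
    FeatureTable,
    TableError,
    make_sample_meta,
    write_feature_table,
    write_json,
    write_sample_meta,
)

EFFECT_TYPES = ("dose_linear", "hrs_shift", "lrs_shift")


@dataclass(frozen=True)
class CohortDesign:
    """Shape of a synthetic crossover cohort.

    The defaults mirror the study conditions this package targets: 23
    subjects in the low-carbohydrate arm, three samples per subject
    (baseline day 14, then the two RS diets in crossover order).  Feature
    counts are desk-scale stand-ins for the real layer sizes.
    """

    n_subjects: int = 23
    arm_split: float = 1.0  # fraction of subjects in the LC arm
    diets: tuple[str, ...] = ("baseline", "LRS", "HRS")
    n_otus: int = 120
    n_proteins: int = 100
    n_metabolites: int = 150
    seed: int = 0

    # free parameters of the noise model (documented, not calibrated)
    otu_depth_log_mean: float = np.log(20_000.0)
    otu_depth_log_sd: float = 0.3
    otu_dispersion: float = 5.0
    protein_depth_log_mean: float = np.log(6_000.0)
    protein_depth_log_sd: float = 0.5
    protein_dispersion: float = 3.0
    metabolite_log_sd: float = 0.4
    metabolite_missing_rate: float = 0.2
    subject_sd: float = 0.5  # per-subject random intercept (log scale)
    feature_sd: float = 1.2  # spread of baseline feature abundances (log scale)

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if not 0.0 <= self.arm_split <= 1.0:
            raise ValueError("arm_split must lie in [0, 1]")
        unknown = set(self.diets) - set(RS_DOSE)
        if unknown:
            raise ValueError(f"unknown diet labels {sorted(unknown)}")

    def n_features(self, layer: str) -> int:
        return {"otu": self.n_otus, "protein": self.n_proteins,
                "metabolite": self.n_metabolites}[layer]


@dataclass(frozen=True)
class PlantedEffect:
    """A known abundance effect injected into one feature.

    ``magnitude`` acts multiplicatively on the expected value, on the log
    scale: a ``dose_linear`` effect multiplies the mean by
    ``exp(magnitude * dose)`` at coded dose 0 / 0.05 / 1, so it is monotone
    in dose; ``hrs_shift``/``lrs_shift`` multiply by ``exp(magnitude)`` in
    that diet only.  Features sharing a ``module_id`` additionally load on a
    common per-sample latent factor, creating cross-layer correlation.
    """

    layer: str
    feature_id: str
    effect_type: str
    magnitude: float
    module_id: int | None = None

    def __post_init__(self) -> None:
        if self.effect_type not in EFFECT_TYPES:
            raise ValueError(
                f"unknown effect_type {self.effect_type!r}; expected {EFFECT_TYPES}"
            )
        if not np.isfinite(self.magnitude):
            raise ValueError("magnitude must be finite")


@dataclass
class SyntheticTruth:
    """Ground truth of a generated cohort."""

    effects: list[PlantedEffect]
    module_map: dict[tuple[str, str], int]
    baseline_params: dict[str, dict[str, dict[str, float]]]

    def module_members(self, module_id: int) -> list[tuple[str, str]]:
        return sorted(k for k, m in self.module_map.items() if m == module_id)

    def to_jsonable(self) -> dict:
        return {
            "effects": [
                {
                    "layer": e.layer,
                    "feature_id": e.feature_id,
                    "effect_type": e.effect_type,
                    "magnitude": e.magnitude,
                    "module_id": e.module_id,
                }
                for e in self.effects
            ],
            "module_map": {
                f"{layer}:{fid}": mid for (layer, fid), mid in self.module_map.items()
            },
            "baseline_params": self.baseline_params,
        }


def _feature_ids(layer: str, n: int) -> list[str]:
    prefix = {"otu": "OTU", "protein": "PROT", "metabolite": "MET"}[layer]
    width = max(4, len(str(n)))
    return [f"{prefix}_{i + 1:0{width}d}" for i in range(n)]


def _diet_multiplier(effect: PlantedEffect, diet: str) -> float:
    dose = RS_DOSE[diet]
    if effect.effect_type == "dose_linear":
        return float(np.exp(effect.magnitude * dose))
    if effect.effect_type == "hrs_shift":
        return float(np.exp(effect.magnitude)) if diet == "HRS" else 1.0
    return float(np.exp(effect.magnitude)) if diet == "LRS" else 1.0


def generate_cohort(
    design: CohortDesign,
    effects: Sequence[PlantedEffect] = (),
) -> tuple[dict[str, FeatureTable], pd.DataFrame, SyntheticTruth]:
    """Generate the three layer tables, sample metadata, and ground truth.

    Identical ``(design, effects)`` yields bit-identical output.  Effects
    referencing an unknown layer or feature are rejected up front.
    """
    rng = np.random.default_rng(design.seed)

    feature_ids = {layer: _feature_ids(layer, design.n_features(layer))
                   for layer in ("otu", "protein", "metabolite")}
    for eff in effects:
        if eff.layer not in feature_ids:
            raise TableError(
                f"planted effect references unknown layer {eff.layer!r}"
            )
        if eff.feature_id not in feature_ids[eff.layer]:
            raise TableError(
                f"planted effect references unknown feature {eff.feature_id!r} "
                f"in layer {eff.layer!r}"
            )

    # --- study design: subjects, arms, samples --------------------------
    n_lc = int(round(design.arm_split * design.n_subjects))
    subjects = [f"S{i + 1:03d}" for i in range(design.n_subjects)]
    arms = {s: ("LC" if i < n_lc else "HC") for i, s in enumerate(subjects)}
    # crossover: half the subjects take HRS first (day 28), half LRS first
    day_of = {}
    for i, subj in enumerate(subjects):
        first, second = ("HRS", "LRS") if i % 2 == 0 else ("LRS", "HRS")
        day_of[subj] = {"baseline": 14, first: 28, second: 56}
    records = []
    for subj in subjects:
        for diet in design.diets:
            records.append(
                {
                    "sample_id": f"{subj}-{diet}",
                    "subject_id": subj,
                    "arm": arms[subj],
                    "diet": diet,
                    "day": day_of[subj][diet],
                }
            )
    meta = make_sample_meta(records)
    n_samples = len(meta)

    # --- planted-structure bookkeeping ----------------------------------
    effect_of: dict[tuple[str, str], PlantedEffect] = {}
    module_map: dict[tuple[str, str], int] = {}
    for eff in effects:
        key = (eff.layer, eff.feature_id)
        if key in effect_of:
            raise TableError(f"feature {key} carries more than one planted effect")
        effect_of[key] = eff
        if eff.module_id is not None:
            module_map[key] = eff.module_id

    # one latent factor per module per sample, shared across layers
    module_ids = sorted({m for m in module_map.values()})
    latent = {m: rng.standard_normal(n_samples) for m in module_ids}

    tables: dict[str, FeatureTable] = {}
    baseline_params: dict[str, dict[str, dict[str, float]]] = {}

    for layer in ("otu", "protein", "metabolite"):
        fids = feature_ids[layer]
        p = len(fids)
        base_log = rng.normal(0.0, design.feature_sd, size=p)
        subj_int = rng.normal(0.0, design.subject_sd, size=(design.n_subjects, p))
        subj_index = {s: i for i, s in enumerate(subjects)}

        log_mu = np.empty((n_samples, p))
        for row, rec in meta.iterrows():
            log_mu[row] = base_log + subj_int[subj_index[rec["subject_id"]]]
            for j, fid in enumerate(fids):
                eff = effect_of.get((layer, fid))
                if eff is None:
                    continue
                log_mu[row, j] += np.log(_diet_multiplier(eff, rec["diet"]))
                if eff.module_id is not None:
                    log_mu[row, j] += eff.magnitude * latent[eff.module_id][row]

        if layer in ("otu", "protein"):
            if layer == "otu":
                depth_mu, depth_sd = design.otu_depth_log_mean, design.otu_depth_log_sd
                dispersion = design.otu_dispersion
            else:
                depth_mu, depth_sd = (
                    design.protein_depth_log_mean,
                    design.protein_depth_log_sd,
                )
                dispersion = design.protein_dispersion
            depths = np.exp(rng.normal(depth_mu, depth_sd, size=n_samples))
            rel = np.exp(log_mu)
            rel /= rel.sum(axis=1, keepdims=True)
            mu = rel * depths[:, None]
            prob = dispersion / (dispersion + mu)
            counts = rng.negative_binomial(dispersion, prob).astype(float)
            matrix = counts
            baseline_params[layer] = {
                fid: {"log_mean": float(base_log[j]), "dispersion": float(dispersion)}
                for j, fid in enumerate(fids)
            }
        else:
            noise = rng.normal(0.0, design.metabolite_log_sd, size=(n_samples, p))
            intensity = np.exp(log_mu + noise) * 1.0e6
            drop = rng.random((n_samples, p)) < design.metabolite_missing_rate
            intensity[drop] = 0.0
            matrix = intensity
            baseline_params[layer] = {
                fid: {
                    "log_mean": float(base_log[j]),
                    "log_sd": float(design.metabolite_log_sd),
                }
                for j, fid in enumerate(fids)
            }

        data = pd.DataFrame(matrix, index=list(meta["sample_id"]), columns=fids)
        data.index.name = "sample_id"
        tables[layer] = FeatureTable(layer, data)

    truth = SyntheticTruth(list(effects), module_map, baseline_params)
    return tables, meta, truth


# ---------------------------------------------------------------------------
# Peak-list emulation for the FT-ICR-MS alignment stage
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SnrModel:
    """Log-normal S/N model: S/N = exp(N(log(median), sigma))."""

    median: float = 20.0
    sigma: float = 0.5


def generate_peaklists(
    table: FeatureTable,
    mz_assignment: Mapping[str, float],
    ppm_jitter: float = 0.3,
    snr_model: SnrModel = SnrModel(),
    seed: int = 0,
) -> list["PeakList"]:
    """Explode a metabolite table into per-sample (m/z, intensity, S/N) lists.

    Each non-missing, non-zero intensity becomes one peak whose m/z is the
    assigned value perturbed uniformly within ``±ppm_jitter``.  Assignments
    closer than 3× the jitter are rejected, since alignment could not
    possibly resolve them afterwards.
    """
    from .metabolomics import PeakList  # local import to avoid a cycle

    if table.layer != "metabolite":
        raise TableError("peak lists are generated from the metabolite layer")
    if ppm_jitter < 0:
        raise ValueError("ppm_jitter must be >= 0")
    missing = [f for f in table.feature_ids if f not in mz_assignment]
    if missing:
        raise TableError(f"mz_assignment lacks features {missing[:3]}")

    mzs = sorted(float(mz_assignment[f]) for f in table.feature_ids)
    for lo, hi in zip(mzs, mzs[1:]):
        gap_ppm = (hi - lo) / ((hi + lo) / 2.0) * 1e6
        if ppm_jitter > 0 and gap_ppm < 3.0 * ppm_jitter:
            raise TableError(
                f"assigned m/z {lo} and {hi} are {gap_ppm:.3g} ppm apart, "
                f"closer than 3x the jitter ({3 * ppm_jitter:.3g} ppm)"
            )

    rng = np.random.default_rng(seed)
    values = table.values()
    peaklists = []
    for i, sid in enumerate(table.sample_ids):
        peaks = []
        for j, fid in enumerate(table.feature_ids):
            inten = values[i, j]
            if np.isnan(inten) or inten == 0.0:
                continue
            mz = float(mz_assignment[fid])
            jitter = rng.uniform(-ppm_jitter, ppm_jitter) * 1e-6 * mz
            snr = float(np.exp(rng.normal(np.log(snr_model.median), snr_model.sigma)))
            peaks.append((mz + jitter, float(inten), snr))
        peaklists.append(PeakList(sample_id=sid, peaks=peaks))
    return peaklists


def default_mz_assignment(
    feature_ids: Sequence[str],
    start: float = 150.0,
    spacing_ppm: float = 50.0,
) -> dict[str, float]:
    """Assign synthetic m/z values spaced a fixed number of ppm apart."""
    out = {}
    mz = start
    for fid in sorted(feature_ids):
        out[fid] = round(mz, 6)
        mz *= 1.0 + spacing_ppm * 1e-6
    return out


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_cohort(
    outdir: str | Path,
    tables: Mapping[str, FeatureTable],
    meta: pd.DataFrame,
    truth: SyntheticTruth,
) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for layer, table in tables.items():
        write_feature_table(table, outdir / f"{layer}_table.tsv")
    write_sample_meta(meta, outdir / "sample_meta.tsv")
    write_json(truth.to_jsonable(), outdir / "truth.json")
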