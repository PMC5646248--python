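"""Direct-infusion FT-ICR-MS preprocessing and exact-mass arithmetic.

Covers the metabolite-layer preparation steps: S/N filtering of exported
peak lists, cross-sample peak alignment at ppm tolerance, occurrence and
mass-defect filters on the aligned matrix, monoisotopic-mass and adduct
arithmetic for ion assignment, and external-calibration quantification of
short-chain fatty acids.

Mass conventions
----------------
Atomic masses of the most abundant isotopes are pinned in one constants
table (``ATOMIC_MASSES``).  Deprotonation ([M−H]⁻) subtracts the proton
mass 1.007276 Da (hydrogen atom minus electron).  The AMP⁺ charge-tag
arithmetic for derivatized carboxylic acids is

    m/z = M − H₂O + C₁₂H₁₃N₂

using plain atomic-mass sums for the cation with no electron-mass
correction; that convention reproduces the published calibration masses of
the derivatized acids to 4 decimal places.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .tables import FeatureTable, TableError

# most-abundant-isotope atomic masses (Da); single source of truth
ATOMIC_MASSES: Mapping[str, float] = {
    "C": 12.0,
    "H": 1.00782503,
    "N": 14.00307401,
    "O": 15.99491462,
    "S": 31.97207117,
    "P": 30.97376200,
}

#: proton mass (H atom minus electron), used for [M−H]⁻ / [M+H]⁺ arithmetic
PROTON_MASS = 1.007276

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str | Mapping[str, int]) -> dict[str, int]:
    """Parse ``"C4H8O2"`` (or pass through an element→count map)."""
    if isinstance(formula, Mapping):
        counts = {str(k): int(v) for k, v in formula.items()}
    else:
        counts = {}
        pos = 0
        for match in _FORMULA_TOKEN.finditer(formula):
            if match.start() != pos:
                raise TableError(f"unparseable formula {formula!r}")
            if not match.group(0):
                break
            element, digits = match.groups()
            counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
            pos = match.end()
        if pos != len(formula):
            raise TableError(f"unparseable formula {formula!r}")
    if not counts:
        raise TableError("empty elemental formula")
    for element, n in counts.items():
        if n <= 0:
            raise TableError(f"non-positive count for element {element!r}")
    return counts


def monoisotopic_mass(formula: str | Mapping[str, int]) -> float:
    """Monoisotopic (most-abundant-isotope) mass of a neutral formula, Da."""
    counts = parse_formula(formula)
    unknown = set(counts) - set(ATOMIC_MASSES)
    if unknown:
        raise TableError(f"unsupported element(s) {sorted(unknown)}")
    return float(sum(ATOMIC_MASSES[el] * n for el, n in counts.items()))


def deprotonated_mz(formula: str | Mapping[str, int]) -> float:
    """[M−H]⁻ m/z: monoisotopic mass minus the proton mass."""
    counts = parse_formula(formula)
    if counts.get("H", 0) < 1:
        raise TableError("cannot deprotonate a formula without hydrogen")
    return monoisotopic_mass(counts) - PROTON_MASS


_H2O = 2 * ATOMIC_MASSES["H"] + ATOMIC_MASSES["O"]
_AMP_CATION = 12 * ATOMIC_MASSES["C"] + 13 * ATOMIC_MASSES["H"] + 2 * ATOMIC_MASSES["N"]


def amp_adduct_mz(formula: str | Mapping[str, int]) -> float:
    """m/z of the AMP⁺-derivatized acid: M − H₂O + C₁₂H₁₃N₂ (atomic sums)."""
    return monoisotopic_mass(formula) - _H2O + _AMP_CATION


# ---------------------------------------------------------------------------
# Peak lists
# ---------------------------------------------------------------------------


@dataclass
class PeakList:
    """Per-sample (m/z, intensity[, S/N]) triples, sorted ascending by m/z."""

    sample_id: str
    peaks: list[tuple]  # (mz, intensity) or (mz, intensity, snr)

    def __post_init__(self) -> None:
        for peak in self.peaks:
            if peak[0] <= 0:
                raise TableError(f"non-positive m/z {peak[0]} in {self.sample_id!r}")
            if peak[1] < 0:
                raise TableError(f"negative intensity in {self.sample_id!r}")
        self.peaks = sorted(self.peaks, key=lambda p: p[0])

    @property
    def has_snr(self) -> bool:
        return all(len(p) >= 3 for p in self.peaks)

    def __len__(self) -> int:
        return len(self.peaks)


def read_peaklist(path: str | Path, sample_id: str | None = None) -> PeakList:
    """Read a whitespace-delimited ASCII peak list (m/z intensity [snr]).

    Lines starting with ``#`` are comments.  The sample ID defaults to the
    file stem.
    """
    path = Path(path)
    peaks = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.split()
        if len(fields) < 2:
            raise TableError(f"{path}:{lineno}: expected m/z and intensity")
        try:
            numbers = tuple(float(x) for x in fields[:3])
        except ValueError:
            raise TableError(f"{path}:{lineno}: non-numeric field") from None
        peaks.append(numbers)
    return PeakList(sample_id=sample_id or path.stem, peaks=peaks)


def write_peaklist(peaklist: PeakList, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("# m/z\tintensity" + ("\tsnr" if peaklist.has_snr else "") + "\n")
        for peak in peaklist.peaks:
            fh.write("\t".join(format(x, ".10g") for x in peak) + "\n")


def filter_snr(peaklist: PeakList, min_snr: float = 4.0) -> PeakList:
    """Keep peaks with S/N ≥ ``min_snr`` (a peak *at* the export threshold
    is kept)."""
    if not peaklist.has_snr:
        raise TableError(
            f"peak list {peaklist.sample_id!r} carries no S/N column; "
            "skip the S/N filtering stage"
        )
    kept = [p for p in peaklist.peaks if p[2] >= min_snr]
    return PeakList(sample_id=peaklist.sample_id, peaks=kept)


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------


def _consensus(mzs: np.ndarray, intensities: np.ndarray) -> float:
    weights = intensities.copy()
    if weights.sum() <= 0:
        weights = np.ones_like(weights)
    return float(np.average(mzs, weights=weights))


def _split_segments(order: np.ndarray, mzs: np.ndarray, intens: np.ndarray,
                    ppm_tol: float) -> list[np.ndarray]:
    """Recursively split an m/z-sorted index block into tolerance-consistent
    groups.

    A block is cut wherever the gap between adjacent peaks exceeds the
    tolerance (relative to the gap midpoint); any remaining block whose
    members stray beyond the tolerance from the intensity-weighted consensus
    is split at its largest internal gap.  Deterministic and independent of
    input sample order.
    """
    segments: list[np.ndarray] = []
    stack = [order]
    while stack:
        block = stack.pop()
        if len(block) == 1:
            segments.append(block)
            continue
        m = mzs[block]
        gaps_ppm = np.diff(m) / ((m[:-1] + m[1:]) / 2.0) * 1e6
        cut = np.where(gaps_ppm > ppm_tol)[0]
        if len(cut):
            pieces = np.split(block, cut + 1)
            stack.extend(pieces)
            continue
        consensus = _consensus(m, intens[block])
        dev_ppm = np.abs(m - consensus) / consensus * 1e6
        if (dev_ppm <= ppm_tol).all():
            segments.append(block)
        else:
            largest = int(np.argmax(gaps_ppm))
            stack.append(block[: largest + 1])
            stack.append(block[largest + 1:])
    segments.sort(key=lambda b: mzs[b[0]])
    return segments


def align_peaks(
    peaklists: Sequence[PeakList], ppm_tol: float = 1.0
) -> FeatureTable:
    """Align per-sample peak lists into a metabolite FeatureTable.

    Peaks from all samples are pooled and sorted by m/z; the sorted sequence
    is cut wherever the gap between adjacent peaks exceeds ``ppm_tol``, and
    any group violating the member-to-consensus tolerance is split at its
    largest gap.  A sample contributes at most one peak per group (closest
    to the consensus wins).  Feature IDs are the intensity-weighted
    consensus m/z at 5 decimal places; absence is a missing marker, not a
    zero.  Per-feature member counts are recorded in ``feature_meta``.
    """
    if not peaklists:
        raise TableError("align_peaks requires at least one peak list")
    sample_ids = [pl.sample_id for pl in peaklists]
    if len(set(sample_ids)) != len(sample_ids):
        raise TableError("duplicate sample IDs among peak lists")

    rows = []
    for si, pl in enumerate(peaklists):
        for peak in pl.peaks:
            rows.append((peak[0], peak[1], si))
    n_samples = len(sample_ids)
    if not rows:
        data = pd.DataFrame(index=sample_ids, columns=[], dtype=float)
        data.index.name = "sample_id"
        return FeatureTable("metabolite", data)

    mzs = np.array([r[0] for r in rows])
    intens = np.array([r[1] for r in rows])
    samples = np.array([r[2] for r in rows])
    # stable order: by m/z, ties broken by sorted sample id then intensity
    order = np.lexsort((intens, samples, mzs))

    segments = _split_segments(order, mzs, intens, ppm_tol)

    matrix = np.full((n_samples, len(segments)), np.nan)
    feature_ids: list[str] = []
    member_counts: list[int] = []
    for j, seg in enumerate(segments):
        consensus = _consensus(mzs[seg], intens[seg])
        kept = 0
        for si in np.unique(samples[seg]):
            members = seg[samples[seg] == si]
            best = members[np.argmin(np.abs(mzs[members] - consensus))]
            matrix[si, j] = intens[best]
            kept += 1
        fid = format(consensus, ".5f")
        while fid in feature_ids:  # guard against 5-dp collisions
            fid += "0"
        feature_ids.append(fid)
        member_counts.append(int(len(seg)))

    data = pd.DataFrame(matrix, index=sample_ids, columns=feature_ids)
    data.index.name = "sample_id"
    meta = pd.DataFrame({"member_count": member_counts}, index=feature_ids)
    return FeatureTable("metabolite", data, feature_meta=meta)


def filter_occurrence(table: FeatureTable, min_occurrence: int = 5) -> FeatureTable:
    """Keep mass signals observed (non-missing) in ≥ ``min_occurrence``
    spectra; signals counted fewer times are removed."""
    observed = (~table.data.isna()).sum(axis=0)
    keep = [f for f in table.feature_ids if observed[f] >= min_occurrence]
    return table.select_features(keep)


def filter_mass_defect(table: FeatureTable, max_defect: float = 0.8) -> FeatureTable:
    """Remove mass signals whose fractional m/z part exceeds ``max_defect``.

    Requires feature IDs that parse as m/z values.  In this mass range a
    mass defect above 0.8 marks non-biological signals.
    """
    keep = []
    for fid in table.feature_ids:
        try:
            mz = float(fid)
        except ValueError:
            raise TableError(f"feature ID {fid!r} is not an m/z value") from None
        if mz - np.floor(mz) <= max_defect:
            keep.append(fid)
    return table.select_features(keep)


# ---------------------------------------------------------------------------
# External calibration (SCFA quantification)
# ---------------------------------------------------------------------------


@dataclass
class CalibrationCurve:
    """OLS calibration line: response = slope · concentration + intercept."""

    analyte: str
    slope: float
    intercept: float
    r_squared: float
    channel: str = "MS"  # detection channel: UV | MS


def fit_calibration(
    points: Sequence[tuple[float, float]],
    analyte: str = "",
    channel: str = "MS",
) -> CalibrationCurve:
    """Ordinary least squares fit of response on concentration."""
    conc = np.array([p[0] for p in points], dtype=float)
    resp = np.array([p[1] for p in points], dtype=float)
    if len(np.unique(conc)) < 2:
        raise TableError("calibration needs >= 2 distinct concentrations")
    fit = stats.linregress(conc, resp)
    return CalibrationCurve(
        analyte=analyte,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        channel=channel,
    )


def quantify(curve: CalibrationCurve, response: float) -> float:
    """Invert the calibration line: concentration = (response − b) / a."""
    if curve.slope == 0:
        raise TableError(f"calibration for {curve.analyte!r} has zero slope")
    return (response - curve.intercept) / curve.slope


# ---------------------------------------------------------------------------
# Annotation bookkeeping
# ---------------------------------------------------------------------------

ANNOTATION_CATEGORIES = ("formula_only", "compound", "pathway_listed", "none")


def annotation_summary(
    table: FeatureTable, annotations: Mapping[str, str]
) -> dict[str, dict[str, float]]:
    """Percentage of features per annotation category (integer-rounded).

    Every feature must carry one of ``formula_only`` (formula assigned but
    compound unknown), ``compound``, ``pathway_listed``, or ``none``.
    """
    missing = [f for f in table.feature_ids if f not in annotations]
    if missing:
        raise TableError(f"features lacking an annotation category: {missing[:3]}")
    bad = {c for c in annotations.values() if c not in ANNOTATION_CATEGORIES}
    if bad:
        raise TableError(f"unknown annotation categories {sorted(bad)}")
    total = table.n_features
    out: dict[str, dict[str, float]] = {}
    for category in ANNOTATION_CATEGORIES:
        count = sum(1 for f in table.feature_ids if annotations[f] == category)
        out[category] = {
            "count": count,
            "percent": round(100.0 * count / total) if total else 0,
        }
    out["total"] = {"count": total, "percent": 100 if total else 0}
    return out
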