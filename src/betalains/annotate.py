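"""Match screened MS/MS features to catalog records.

Candidates are gathered by precursor mass accuracy (ppm), ranked by
fragment coverage then absolute ppm, checked for agreement with the
fingerprint class call, and iso-epimers sharing a formula are resolved by
retention-time proximity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .catalog import BetalainRecord, Catalog, relative_rt
from .chem import ppm_error
from .fingerprint import (
    CoreIonSet,
    FingerprintConfig,
    FingerprintResult,
    MsmsSpectrum,
    classify_spectrum,
    match_ions,
)

log = logging.getLogger(__name__)

__all__ = [
    "AnnotationConfig",
    "Candidate",
    "AnnotationResult",
    "annotate_feature",
    "annotate_run",
    "resolve_isomers",
    "report",
]

#: class_call -> catalog categories it is compatible with.  ``ambiguous``
#: is compatible with everything and is therefore absent here.
_CALL_COMPAT = {
    "betacyanin": {"betacyanin", "betalamic-acid"},
    "betacyanin-derivative-decarboxy": {"betacyanin-derivative"},
    "betacyanin-derivative-dehydro": {"betacyanin-derivative"},
    "betaxanthin": {"betaxanthin", "betalamic-acid"},
}


@dataclass(frozen=True)
class AnnotationConfig:
    ppm_tol: float = 5.0
    mz_tol: float = 0.01
    min_rel_intensity: float = 0.05
    recalibration_ppm: float = 0.0  # optional global mass-shift correction

    def __post_init__(self) -> None:
        if self.ppm_tol <= 0 or self.mz_tol <= 0:
            raise ValueError("tolerances must be positive")


@dataclass(frozen=True)
class Candidate:
    record: BetalainRecord
    ppm: float
    matched_fragments: int
    coverage: float
    class_agreement: bool


@dataclass(frozen=True)
class AnnotationResult:
    precursor_mz: float
    rt: float
    class_call: str
    candidates: tuple[Candidate, ...]
    accepted: Candidate | None
    reason: str = ""  # why nothing was accepted, when accepted is None


def _agrees(class_call: str, record: BetalainRecord) -> bool:
    compat = _CALL_COMPAT.get(class_call)
    return compat is None or record.category in compat


def resolve_isomers(
    candidates: Sequence[Candidate], rt: float
) -> Candidate | None:
    """Pick among same-formula candidates by retention-time proximity.

    Returns ``None`` when two catalog retention times are exactly
    equidistant from the feature (reported as ambiguous rather than
    guessed).  If no candidate has a usable retention time, the
    non-"iso"-prefixed name is preferred (the earlier-eluting epimer).
    """
    if len(candidates) == 1:
        return candidates[0]
    with_rt = [c for c in candidates if not math.isnan(c.record.rt)]
    if not with_rt:
        non_iso = [c for c in candidates if not c.record.name.lower().startswith("iso")]
        return non_iso[0] if non_iso else candidates[0]
    distances = sorted((abs(c.record.rt - rt), c.record.id, c) for c in with_rt)
    if len(distances) > 1 and distances[0][0] == distances[1][0]:
        return None
    return distances[0][2]


def annotate_feature(
    spectrum: MsmsSpectrum,
    catalog: Catalog,
    fp: FingerprintResult | None = None,
    cfg: AnnotationConfig = AnnotationConfig(),
    fp_cfg: FingerprintConfig = FingerprintConfig(),
    ions: CoreIonSet = CoreIonSet(),
) -> AnnotationResult:
    """Annotate one screened feature against the catalog.

    Candidates within the ppm tolerance are ranked by (class agreement,
    fragment coverage desc, |ppm| asc, catalog id); candidates whose
    category contradicts the fingerprint class call are demoted, never
    silently accepted.
    """
    if not len(catalog):
        raise ValueError("catalog is empty")
    if fp is None:
        fp = classify_spectrum(spectrum, ions, fp_cfg)

    observed = spectrum.precursor_mz * (1.0 - cfg.recalibration_ppm * 1e-6)
    candidates: list[Candidate] = []
    for record in catalog:
        ppm = ppm_error(observed, record.theoretical_mz)
        if abs(ppm) > cfg.ppm_tol:
            continue
        matched = match_ions(
            spectrum, record.fragments, cfg.mz_tol, cfg.min_rel_intensity
        )
        coverage = len(matched) / len(record.fragments) if record.fragments else 0.0
        candidates.append(
            Candidate(
                record=record,
                ppm=ppm,
                matched_fragments=len(matched),
                coverage=coverage,
                class_agreement=_agrees(fp.class_call, record),
            )
        )
    candidates.sort(
        key=lambda c: (not c.class_agreement, -c.coverage, abs(c.ppm), c.record.id)
    )

    if not candidates:
        return AnnotationResult(
            spectrum.precursor_mz, spectrum.rt, fp.class_call, (), None,
            reason="no catalog record within ppm tolerance",
        )
    best = candidates[0]
    if not best.class_agreement:
        return AnnotationResult(
            spectrum.precursor_mz, spectrum.rt, fp.class_call, tuple(candidates), None,
            reason=(
                f"best candidate {best.record.name!r} contradicts "
                f"class call {fp.class_call!r}"
            ),
        )
    # Same-formula records tied on coverage are epimers/positional isomers:
    # only retention time can separate them.
    tied = [
        c
        for c in candidates
        if c.class_agreement
        and c.record.formula == best.record.formula
        and abs(c.coverage - best.coverage) < 1e-9
    ]
    accepted = resolve_isomers(tied, spectrum.rt)
    if accepted is None:
        return AnnotationResult(
            spectrum.precursor_mz, spectrum.rt, fp.class_call, tuple(candidates), None,
            reason="equidistant same-formula candidates (ambiguous)",
        )
    return AnnotationResult(
        spectrum.precursor_mz, spectrum.rt, fp.class_call, tuple(candidates), accepted
    )


def annotate_run(
    spectra: Iterable[MsmsSpectrum],
    catalog: Catalog,
    cfg: AnnotationConfig = AnnotationConfig(),
    fp_cfg: FingerprintConfig = FingerprintConfig(),
    ions: CoreIonSet = CoreIonSet(),
) -> list[AnnotationResult]:
    """Screen and annotate a whole run; rejected features are logged."""
    results = []
    for spectrum in spectra:
        fp = classify_spectrum(spectrum, ions, fp_cfg)
        if fp.class_call == "not-betalain":
            log.info(
                "feature m/z %.4f rt %.2f rejected: fewer than %d core ions",
                spectrum.precursor_mz, spectrum.rt, fp_cfg.min_core,
            )
            continue
        result = annotate_feature(spectrum, catalog, fp, cfg, fp_cfg, ions)
        if result.accepted is None:
            log.info(
                "feature m/z %.4f rt %.2f not annotated: %s",
                spectrum.precursor_mz, spectrum.rt, result.reason,
            )
        results.append(result)
    return results


def report(
    annotations: Iterable[AnnotationResult],
    catalog: Catalog,
    areas: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Annotation report mirroring the reference-table columns.

    Relative Rt is computed against the run's own reference-compound
    feature when one was annotated, otherwise against the catalog
    reference (flagged in ``rt_reference``).  Peak areas, when supplied
    (keyed by compound name), are copied through verbatim.
    """
    accepted = [a for a in annotations if a.accepted is not None]
    ref_name = catalog.reference_compound
    run_ref_rt = next(
        (a.rt for a in accepted if a.accepted.record.name == ref_name), None
    )
    if run_ref_rt is not None:
        ref_rt, ref_source = run_ref_rt, "run"
    else:
        ref = catalog.reference_record
        ref_rt = ref.rt if ref is not None else None
        ref_source = "catalog"
    rows = []
    for a in sorted(accepted, key=lambda a: (a.rt, a.precursor_mz)):
        record = a.accepted.record
        rows.append(
            {
                "compound": record.name,
                "class": record.betalain_class.name,
                "category": record.category,
                "rt_min": a.rt,
                "relative_rt": relative_rt(a.rt, ref_rt) if ref_rt else math.nan,
                "rt_reference": ref_source,
                "formula": str(record.formula),
                "theoretical_mz": record.theoretical_mz,
                "observed_mz": a.precursor_mz,
                "ppm": a.accepted.ppm,
                "matched_fragments": a.accepted.matched_fragments,
                "coverage": a.accepted.coverage,
                "class_call": a.class_call,
                "tentative": record.tentative,
                "area": (areas or {}).get(record.name, math.nan),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "compound", "class", "category", "rt_min", "relative_rt",
            "rt_reference", "formula", "theoretical_mz", "observed_mz", "ppm",
            "matched_fragments", "coverage", "class_call", "tentative", "area",
        ],
    )
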