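"""Annotation: database search, precursor-fragment linking, neutral-loss
sugar assignment and O-/C-glycosylation classification.

The flow mirrors how a DIA flavonoid profile is read by hand:

1. MS1 features are matched against compound databases (neutral-mass basis,
   adduct-aware).
2. MS2 features are matched against the in-silico aglycone-fragment
   database.
3. Each annotated fragment is linked to candidate precursors that co-elute
   and share the chromatographic peak shape.
4. The neutral loss (precursor m/z minus fragment m/z) is looked up in the
   glycosyl-loss dictionary — with the one-hydrogen radical correction for
   homolytic fragments — giving the final report string, e.g.
   ``"Quercetin O-hexoside"``.  Sugar *position* is deliberately never
   assigned; m/z alone cannot support it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import chemcore
from .chemcore import (
    AdductDef,
    FragmentRecord,
    SugarLossDef,
    adduct_mz,
    neutral_loss,
    ppm_error,
)
from .dbio import CompoundRecord
from .featdet import AlignedRow, AlignedTable

__all__ = [
    "Annotation",
    "LinkedPair",
    "GlycosideAnnotation",
    "AGLYCONE_CLASSES",
    "search_ms1",
    "search_ms2",
    "link_precursor_fragment",
    "assign_glycoside",
    "annotate_tables",
    "jaccard_isomer_score",
    "classify_backbone",
    "annotation_frame",
]

#: Flavonoid class per aglycone backbone (exact-mass isomers share a row in
#: the databases but may differ in class; reported name wins).
AGLYCONE_CLASSES: Dict[str, str] = {
    "Kaempferol": "flavonol",
    "Datiscetin": "flavonol",
    "Luteolin": "flavone",
    "Quercetin": "flavonol",
    "Myricetin": "flavonol",
    "Apigenin": "flavone",
    "Naringenin": "flavanone",
    "Taxifolin": "flavanonol",
    "Catechin": "flavan-3-ol",
    "Epicatechin": "flavan-3-ol",
}


@dataclass
class Annotation:
    """A database hit on one aligned feature row."""

    row_index: int
    record: object  # CompoundRecord | FragmentRecord
    theoretical_mz: float
    ppm: float
    adduct: Optional[AdductDef] = None
    rank: int = 0


def _search_window(mz: float, tol_abs: float, tol_ppm: float) -> float:
    return max(tol_abs, tol_ppm * 1e-6 * mz)


def search_ms1(
    table: AlignedTable,
    db: Sequence[CompoundRecord],
    adducts: Optional[Sequence[AdductDef]] = None,
    tol_abs: float = 0.005,
    tol_ppm: float = 5.0,
    rt_tol: Optional[float] = None,
) -> List[Annotation]:
    """Adduct-aware local database search on the MS1 feature table.

    All (record, adduct) combinations whose computed m/z falls within the
    search window are returned, ranked per row by absolute ppm error.
    Records flagged RT-wildcard match at any retention time; otherwise the
    record RT must fall within ``rt_tol`` of the row (when given).
    """
    if not db:
        raise ValueError("empty compound database")
    adducts = list(adducts) if adducts is not None else chemcore.expand_adducts()
    out: List[Annotation] = []
    for ri, row in enumerate(table.rows):
        hits: List[Annotation] = []
        window = _search_window(row.mz, tol_abs, tol_ppm)
        for rec in db:
            if not rec.rt_wildcard and rec.rt is not None and rt_tol is not None:
                if abs(rec.rt - row.rt) > rt_tol:
                    continue
            for ad in adducts:
                theo = adduct_mz(rec.mass, ad)
                if abs(row.mz - theo) <= window:
                    hits.append(
                        Annotation(ri, rec, theo, ppm_error(row.mz, theo), adduct=ad)
                    )
        hits.sort(key=lambda a: (abs(a.ppm), a.record.name))
        for rank, h in enumerate(hits):
            h.rank = rank
        out.extend(hits)
    return out


def search_ms2(
    table: AlignedTable,
    fragdb: Sequence[FragmentRecord],
    tol_abs: float = 0.005,
    tol_ppm: float = 5.0,
) -> List[Annotation]:
    """Match MS2 feature rows against the aglycone-fragment database (the
    fragment m/z values are already on the [M - H]- basis)."""
    if not fragdb:
        raise ValueError("empty fragment database")
    out: List[Annotation] = []
    for ri, row in enumerate(table.rows):
        window = _search_window(row.mz, tol_abs, tol_ppm)
        hits = [
            Annotation(ri, rec, rec.mz, ppm_error(row.mz, rec.mz))
            for rec in fragdb
            if abs(row.mz - rec.mz) <= window
        ]
        hits.sort(key=lambda a: (abs(a.ppm), a.record.label))
        for rank, h in enumerate(hits):
            h.rank = rank
        out.extend(hits)
    return out


@dataclass
class LinkedPair:
    """A co-eluting, shape-correlated MS1/MS2 feature-row pair."""

    ms1_index: int
    ms2_index: int
    ms1_row: AlignedRow
    ms2_row: AlignedRow
    ms1_mz: float
    ms2_mz: float
    rt: float
    d_rt: float
    correlation: float
    intensity_ratio: float  # fragment / precursor, in the reference sample
    nloss: float
    intensity_warning: bool = False

    @property
    def samples(self) -> Tuple[str, ...]:
        return tuple(sorted(self.ms2_row.members))


def _shape_correlation(f1, f2) -> float:
    """Pearson correlation of two peak traces interpolated onto the shared
    RT grid (union of their sampling points inside the overlap)."""
    lo = max(f1.trace_rt[0], f2.trace_rt[0])
    hi = min(f1.trace_rt[-1], f2.trace_rt[-1])
    if hi <= lo:
        return -1.0
    grid = np.union1d(f1.trace_rt, f2.trace_rt)
    grid = grid[(grid >= lo) & (grid <= hi)]
    if grid.size < 4:
        return -1.0
    a = np.interp(grid, f1.trace_rt, f1.trace_intensity)
    b = np.interp(grid, f2.trace_rt, f2.trace_intensity)
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def link_precursor_fragment(
    ms1: AlignedTable,
    ms2: AlignedTable,
    ms2_rows: Optional[Sequence[int]] = None,
    rt_tol: float = 0.045,
    min_corr: float = 0.8,
) -> List[LinkedPair]:
    """Link annotated MS2 rows to candidate MS1 precursor rows.

    Candidates must co-elute within ``rt_tol`` minutes, have a precursor m/z
    above the fragment m/z, and correlate in peak shape (Pearson on the
    shared RT grid, computed in the most intense sample holding both
    features).  A fragment more intense than its precursor is kept but
    flagged — it usually would display lower intensity.
    """
    targets = sorted(set(ms2_rows)) if ms2_rows is not None else range(len(ms2.rows))
    pairs: List[LinkedPair] = []
    for fi in targets:
        frow = ms2.rows[fi]
        for pi, prow in enumerate(ms1.rows):
            d_rt = frow.rt - prow.rt
            if abs(d_rt) > rt_tol or prow.mz <= frow.mz:
                continue
            common = [s for s in frow.members if s in prow.members]
            if not common:
                continue
            ref = max(common, key=lambda s: prow.members[s].height)
            corr = _shape_correlation(prow.members[ref], frow.members[ref])
            if corr < min_corr:
                continue
            ratio = frow.members[ref].height / prow.members[ref].height
            pairs.append(
                LinkedPair(
                    ms1_index=pi,
                    ms2_index=fi,
                    ms1_row=prow,
                    ms2_row=frow,
                    ms1_mz=prow.mz,
                    ms2_mz=frow.mz,
                    rt=prow.rt,
                    d_rt=float(d_rt),
                    correlation=corr,
                    intensity_ratio=float(ratio),
                    nloss=neutral_loss(prow.mz, frow.mz),
                    intensity_warning=ratio > 1.0,
                )
            )
    return pairs


@dataclass
class GlycosideAnnotation:
    """The final call for one precursor-fragment pair: aglycone, glycosidic
    bond type and sugar moiety."""

    pair: LinkedPair
    aglycone: str
    fragment: FragmentRecord
    bond: str  # "O" | "C" | "unclassified"
    cleavage: str
    sugar: Optional[SugarLossDef]
    sugar_candidates: Tuple[SugarLossDef, ...]
    report: str
    fragment_ppm: float = 0.0
    precursor_candidates: str = ""
    precursor_ppm: Optional[float] = None


def assign_glycoside(
    pair: LinkedPair,
    fragment_annotation: Annotation,
    sugars: Sequence[SugarLossDef] = chemcore.DEFAULT_SUGAR_LOSSES,
    tolerance: float = 0.01,
) -> GlycosideAnnotation:
    """Classify the glycosidic bond and sugar moiety of a linked pair.

    The neutral loss is the MS1 minus MS2 row m/z.  A bare or radical
    aglycone fragment with a matching intact glycosyl loss gives an
    O-glycoside (homolytic fragments shift the expected loss by one
    hydrogen atom); a residue-modified aglycone whose loss decomposes into
    partial sugar losses gives a C-glycoside; anything else is reported
    numerically as unclassified.
    """
    rec = fragment_annotation.record
    if not isinstance(rec, FragmentRecord):
        raise ValueError("pair carries no MS2 aglycone annotation")
    loss = pair.nloss
    radical = rec.cleavage == chemcore.HOMOLYTIC_O
    want_bond = "C" if rec.cleavage == chemcore.C_RESIDUE else "O"
    candidates = tuple(
        c
        for c in chemcore.match_sugar(loss, radical=radical, tolerance=tolerance,
                                      dictionary=sugars)
        if c.bond == want_bond
    )
    if candidates:
        best = candidates[0]
        bond = best.bond
        report = f"{rec.aglycone} {best.name}"
    else:
        best = None
        bond = "unclassified"
        report = f"{rec.aglycone} (neutral loss {loss:.4f} Da)"
    return GlycosideAnnotation(
        pair=pair,
        aglycone=rec.aglycone,
        fragment=rec,
        bond=bond,
        cleavage=rec.cleavage,
        sugar=best,
        sugar_candidates=candidates,
        report=report,
        fragment_ppm=fragment_annotation.ppm,
    )


def annotate_tables(
    ms1: AlignedTable,
    ms2: AlignedTable,
    compound_db: Sequence[CompoundRecord],
    fragment_db: Sequence[FragmentRecord],
    adducts: Optional[Sequence[AdductDef]] = None,
    tol_abs: float = 0.005,
    tol_ppm: float = 5.0,
    link_rt_tol: float = 0.045,
    min_corr: float = 0.8,
    sugars: Sequence[SugarLossDef] = chemcore.DEFAULT_SUGAR_LOSSES,
    sugar_tol: float = 0.01,
) -> Tuple[List[Annotation], List[Annotation], List[LinkedPair], List[GlycosideAnnotation]]:
    """Run the full annotation chain on a pair of aligned tables."""
    ms1_ann = search_ms1(ms1, compound_db, adducts, tol_abs, tol_ppm)
    ms2_ann = search_ms2(ms2, fragment_db, tol_abs, tol_ppm)
    by_ms2_row: Dict[int, List[Annotation]] = {}
    for a in ms2_ann:
        by_ms2_row.setdefault(a.row_index, []).append(a)
    pairs = link_precursor_fragment(
        ms1, ms2, ms2_rows=list(by_ms2_row), rt_tol=link_rt_tol, min_corr=min_corr
    )
    ms1_by_row: Dict[int, List[Annotation]] = {}
    for a in ms1_ann:
        ms1_by_row.setdefault(a.row_index, []).append(a)
    glyco: List[GlycosideAnnotation] = []
    for pair in pairs:
        for frag_ann in by_ms2_row.get(pair.ms2_index, []):
            g = assign_glycoside(pair, frag_ann, sugars=sugars, tolerance=sugar_tol)
            prec = ms1_by_row.get(pair.ms1_index, [])
            # Table-1 style: all precursor candidates reported, joined
            g.precursor_candidates = "; ".join(
                dict.fromkeys(a.record.name for a in prec)
            )
            if prec:
                g.precursor_ppm = prec[0].ppm
            glyco.append(g)
    return ms1_ann, ms2_ann, pairs, glyco


def annotation_frame(glyco: Sequence[GlycosideAnnotation]) -> pd.DataFrame:
    """Annotated pairs as a table mirroring the study-report layout: RT,
    MS1 m/z, precursor candidates, ppm, MS2 m/z, aglycone, ppm, neutral
    loss, bond/sugar call."""
    return pd.DataFrame(
        {
            "rt_min": [round(g.pair.rt, 2) for g in glyco],
            "ms1_mz": [round(g.pair.ms1_mz, 4) for g in glyco],
            "precursor_candidates": [g.precursor_candidates for g in glyco],
            "precursor_ppm": [
                None if g.precursor_ppm is None else round(g.precursor_ppm, 2)
                for g in glyco
            ],
            "ms2_mz": [round(g.pair.ms2_mz, 4) for g in glyco],
            "aglycone_fragment": [g.fragment.label for g in glyco],
            "fragment_ppm": [round(g.fragment_ppm, 2) for g in glyco],
            "neutral_loss": [round(g.pair.nloss, 3) for g in glyco],
            "bond": [g.bond for g in glyco],
            "call": [g.report for g in glyco],
            "shape_correlation": [round(g.pair.correlation, 3) for g in glyco],
            "intensity_warning": [g.pair.intensity_warning for g in glyco],
        }
    )


def jaccard_isomer_score(
    observed: Sequence[float],
    candidates: Mapping[str, Sequence[float]],
    tol: float = 0.01,
) -> List[Tuple[str, float]]:
    """Rank isomer candidates by the Jaccard index of their fragment sets.

    A candidate peak counts as matched when an observed peak lies within
    ``tol`` (one-to-one greedy matching); the score is
    ``|matched| / |union|``.  Used to separate kaempferol/datiscetin from
    luteolin-type isomers by fragmentation pattern rather than precursor
    mass.
    """
    if not len(observed):
        raise ValueError("observed fragment set is empty")
    if not candidates:
        raise ValueError("empty candidate set")
    obs = sorted(observed)
    scored = []
    for name, cand in candidates.items():
        cand = sorted(cand)
        taken = [False] * len(obs)
        matched = 0
        for c in cand:
            best, best_dev = None, None
            for i, o in enumerate(obs):
                if taken[i]:
                    continue
                dev = abs(o - c)
                if dev <= tol and (best_dev is None or dev < best_dev):
                    best, best_dev = i, dev
            if best is not None:
                taken[best] = True
                matched += 1
        union = len(obs) + len(cand) - matched
        scored.append((name, matched / union if union else 0.0))
    scored.sort(key=lambda t: (-t[1], t[0]))
    return scored


def classify_backbone(
    glyco: Sequence[GlycosideAnnotation],
    class_map: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Per-sample hit counts by (aglycone, flavonoid class).

    A pair contributes one count to every sample in which its fragment
    feature was detected.  Returns a samples x (aglycone, class) frame;
    empty input gives an empty frame.
    """
    cmap = dict(AGLYCONE_CLASSES, **(class_map or {}))
    counts: Dict[str, Dict[Tuple[str, str], int]] = {}
    for g in glyco:
        key = (g.aglycone, cmap.get(g.aglycone, "other"))
        for sid in g.pair.samples:
            counts.setdefault(sid, {})[key] = counts.setdefault(sid, {}).get(key, 0) + 1
    if not counts:
        return pd.DataFrame()
    df = pd.DataFrame(counts).T.fillna(0).astype(int)
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["aglycone", "class"])
    df.index.name = "sample"
    return df.sort_index().sort_index(axis=1)
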