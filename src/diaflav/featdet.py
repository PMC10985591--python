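"""Chromatographic feature detection, applied identically at MS1 and MS2.

The central move of the DIA profiling strategy is to run the *same*
feature-detection chain on both acquisition channels: mass detection,
extracted-ion-chromatogram (EIC) building, local-minimum peak resolving,
13C de-isotoping, cross-sample alignment and gap filling.  The low-energy
channel then yields precursor (MS1) features and the high-energy all-ion
channel yields fragment (MS2) features, which are later re-linked by
co-elution.

All tolerances that take both an absolute (Da) and relative (ppm) value use
the *maximum* of the two windows.  Retention times are minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .dbio import MSRun, Spectrum

__all__ = [
    "DetectionConfig",
    "EIC",
    "Feature",
    "AlignedRow",
    "AlignedTable",
    "detect_masses",
    "build_eics",
    "resolve_peaks",
    "deisotope",
    "detect_features",
    "align",
    "gap_fill",
]

ISOTOPE_DELTA = 1.0033548378  # 13C - 12C, Da


@dataclass
class DetectionConfig:
    """Every knob of the detection chain, with the MS1 defaults.

    ``for_ms2()`` derives the MS2 variant, which only lowers the minimum
    absolute height (chromatogram building and peak resolving) to 4e3.
    """

    # mass detection
    noise_level: float = 3e2
    # chromatogram builder
    min_consecutive_scans: int = 5
    min_intensity_consecutive: float = 8e2
    min_height: float = 8e3
    mz_tol_abs: float = 0.005
    mz_tol_ppm: float = 10.0
    eic_max_gap: int = 1  # missing scans tolerated while extending an EIC
    # local-minimum resolver
    chrom_threshold: float = 0.85
    min_rt_search_range: float = 0.035
    min_top_edge_ratio: float = 1.8
    peak_duration: Tuple[float, float] = (0.0, 2.0)
    min_scans: int = 5
    # 13C isotope filter
    iso_mz_tol_abs: float = 0.003
    iso_mz_tol_ppm: float = 5.0
    iso_rt_tol: float = 0.05
    max_charge: int = 1
    # join aligner
    align_mz_tol_abs: float = 0.007
    align_mz_tol_ppm: float = 12.0
    align_mz_weight: float = 3.0
    align_rt_tol: float = 0.045
    align_rt_weight: float = 2.0
    # gap filling
    gapfill_intensity_tol: float = 0.2
    gapfill_mz_tol_abs: float = 0.005
    gapfill_mz_tol_ppm: float = 7.0
    gapfill_rt_tol: float = 0.04
    gapfill_min_scans: int = 4

    def __post_init__(self) -> None:
        for name in (
            "noise_level", "min_intensity_consecutive", "min_height",
            "mz_tol_abs", "mz_tol_ppm", "min_rt_search_range",
            "iso_mz_tol_abs", "iso_rt_tol", "align_mz_tol_abs",
            "align_rt_tol", "gapfill_mz_tol_abs", "gapfill_rt_tol",
        ):
            if getattr(self, name) <= 0 and name != "noise_level":
                raise ValueError(f"DetectionConfig.{name} must be positive")

    def for_ms2(self) -> "DetectionConfig":
        return replace(self, min_height=4e3)

    def mz_window(self, mz: float) -> float:
        return max(self.mz_tol_abs, self.mz_tol_ppm * 1e-6 * mz)

    def iso_window(self, mz: float) -> float:
        return max(self.iso_mz_tol_abs, self.iso_mz_tol_ppm * 1e-6 * mz)

    def align_window(self, mz: float) -> float:
        return max(self.align_mz_tol_abs, self.align_mz_tol_ppm * 1e-6 * mz)

    def gapfill_window(self, mz: float) -> float:
        return max(self.gapfill_mz_tol_abs, self.gapfill_mz_tol_ppm * 1e-6 * mz)


@dataclass
class EIC:
    """An extracted-ion chromatogram: one trace point per matched scan.

    ``scan_pos`` indexes into the ordered scan list *of the EIC's MS level*
    (not the interleaved run), so "consecutive scans" means consecutive
    positions.
    """

    mz: float
    ms_level: int
    scan_pos: np.ndarray
    rt: np.ndarray
    trace_mz: np.ndarray
    intensity: np.ndarray

    def __len__(self) -> int:
        return int(self.scan_pos.size)


@dataclass
class Feature:
    """A resolved chromatographic peak in one sample."""

    sample_id: str
    ms_level: int
    mz: float
    rt: float  # apex, minutes
    height: float
    area: float
    rt_start: float
    rt_end: float
    trace_rt: np.ndarray = field(default_factory=lambda: np.empty(0))
    trace_intensity: np.ndarray = field(default_factory=lambda: np.empty(0))
    gap_filled: bool = False


def detect_masses(spectrum: Spectrum, noise_level: float) -> Tuple[np.ndarray, np.ndarray]:
    """Centroid mass detection: drop peaks at or below the noise level."""
    keep = spectrum.intensity > noise_level
    return spectrum.mz[keep], spectrum.intensity[keep]


def _consecutive_run_ok(scan_pos: np.ndarray, intensity: np.ndarray,
                        min_scans: int, min_intensity: float) -> bool:
    """True if some >= min_scans stretch of consecutive scan positions all
    reach min_intensity."""
    good = intensity >= min_intensity
    run = 0
    prev = None
    for pos, g in zip(scan_pos, good):
        if g and prev is not None and pos == prev + 1 and run > 0:
            run += 1
        elif g:
            run = 1
        else:
            run = 0
        prev = pos if g else None
        if run >= min_scans:
            return True
    return False


def build_eics(run: MSRun, level: int, cfg: DetectionConfig) -> List[EIC]:
    """Intensity-seeded greedy EIC construction at one MS level.

    Centroids surviving mass detection are grouped across scans: seeds are
    taken in order of decreasing intensity (only centroids reaching the
    minimum absolute height can seed — a chromatogram that never reaches it
    is discarded anyway), and each seed is extended scan-by-scan in both
    directions, matching the nearest unused centroid within the m/z window
    of the seed and tolerating up to ``eic_max_gap`` missing scans.  An EIC
    is kept only if it reaches the minimum absolute height and contains a
    stretch of at least ``min_consecutive_scans`` consecutive scans at or
    above ``min_intensity_consecutive``.
    """
    specs = run.spectra_at_level(level)
    n = len(specs)
    scan_mz: List[np.ndarray] = []
    scan_int: List[np.ndarray] = []
    scan_rt = np.array([s.rt for s in specs])
    for s in specs:
        mz, inten = detect_masses(s, cfg.noise_level)
        scan_mz.append(mz)
        scan_int.append(inten)
    used = [np.zeros(m.size, dtype=bool) for m in scan_mz]

    seeds: List[Tuple[float, int, int]] = []
    for i in range(n):
        for j in np.flatnonzero(scan_int[i] >= cfg.min_height):
            seeds.append((float(scan_int[i][j]), i, int(j)))
    seeds.sort(key=lambda t: (-t[0], t[1], t[2]))

    def match_in_scan(i: int, target: float, window: float) -> Optional[int]:
        mz = scan_mz[i]
        if mz.size == 0:
            return None
        lo = np.searchsorted(mz, target - window, side="left")
        hi = np.searchsorted(mz, target + window, side="right")
        best, best_dev = None, None
        for j in range(lo, hi):
            if used[i][j]:
                continue
            dev = abs(mz[j] - target)
            if best_dev is None or dev < best_dev:
                best, best_dev = j, dev
        return best

    eics: List[EIC] = []
    for _, si, sj in seeds:
        if used[si][sj]:
            continue
        target = float(scan_mz[si][sj])
        window = cfg.mz_window(target)
        members: List[Tuple[int, int]] = [(si, sj)]
        used[si][sj] = True
        for direction in (1, -1):
            gap = 0
            i = si + direction
            while 0 <= i < n and gap <= cfg.eic_max_gap:
                j = match_in_scan(i, target, window)
                if j is None:
                    gap += 1
                else:
                    members.append((i, j))
                    used[i][j] = True
                    gap = 0
                i += direction
        members.sort()
        pos = np.array([i for i, _ in members])
        mzs = np.array([scan_mz[i][j] for i, j in members])
        ints = np.array([scan_int[i][j] for i, j in members])
        if ints.max() < cfg.min_height:
            continue
        if not _consecutive_run_ok(pos, ints, cfg.min_consecutive_scans,
                                   cfg.min_intensity_consecutive):
            continue
        rep = float(np.average(mzs, weights=ints))
        eics.append(EIC(rep, level, pos, scan_rt[pos], mzs, ints))
    eics.sort(key=lambda e: (e.mz, e.rt[0]))
    return eics


def _window_minima(rt: np.ndarray, inten: np.ndarray, half_range: float) -> List[int]:
    """Indices that are the strict minimum of their +-half_range RT window."""
    out = []
    for i in range(1, rt.size - 1):
        lo = np.searchsorted(rt, rt[i] - half_range, side="left")
        hi = np.searchsorted(rt, rt[i] + half_range, side="right")
        seg = inten[lo:hi]
        if seg.size >= 3 and inten[i] == seg.min() and i == lo + int(np.argmin(seg)):
            if inten[i] < inten[i - 1] and inten[i] <= inten[i + 1]:
                out.append(i)
    return out


def resolve_peaks(eic: EIC, cfg: DetectionConfig, sample_id: str = "") -> List[Feature]:
    """Local-minimum peak resolving on one EIC.

    Points below the ``1 - chrom_threshold`` intensity quantile of the EIC
    are treated as baseline (they bound peak regions but carry no apex);
    regions are then split at retention-time-windowed local minima, and each
    candidate peak must clear the minimum absolute height, the apex/edge
    ratio, the duration range and the minimum scan count.
    """
    if len(eic) < cfg.min_scans:
        return []
    rt, inten = eic.rt, eic.intensity
    baseline = float(np.quantile(inten, 1.0 - cfg.chrom_threshold))
    above = inten >= baseline
    features: List[Feature] = []
    # maximal runs of above-baseline points, also requiring contiguous scans
    i = 0
    n = rt.size
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while (j + 1 < n and above[j + 1]
               and eic.scan_pos[j + 1] == eic.scan_pos[j] + 1):
            j += 1
        _emit_segments(eic, i, j, cfg, sample_id, features)
        i = j + 1
    return features


def _emit_segments(eic: EIC, lo: int, hi: int, cfg: DetectionConfig,
                   sample_id: str, out: List[Feature]) -> None:
    rt, inten = eic.rt[lo:hi + 1], eic.intensity[lo:hi + 1]
    splits = [0] + [m for m in _window_minima(rt, inten, cfg.min_rt_search_range / 2)
                    ] + [rt.size - 1]
    for a, b in zip(splits[:-1], splits[1:]):
        if b - a + 1 < cfg.min_scans:
            continue
        seg_rt = rt[a:b + 1]
        seg_int = inten[a:b + 1]
        apex = int(np.argmax(seg_int))
        height = float(seg_int[apex])
        if height < cfg.min_height:
            continue
        edge = max(float(seg_int[0]), float(seg_int[-1]))
        if edge > 0 and height / edge < cfg.min_top_edge_ratio:
            continue
        duration = float(seg_rt[-1] - seg_rt[0])
        if not (cfg.peak_duration[0] <= duration <= cfg.peak_duration[1]):
            continue
        seg_mz = eic.trace_mz[lo + a:lo + b + 1]
        out.append(
            Feature(
                sample_id=sample_id,
                ms_level=eic.ms_level,
                mz=float(np.average(seg_mz, weights=seg_int)),
                rt=float(seg_rt[apex]),
                height=height,
                area=float(np.trapezoid(seg_int, seg_rt)),
                rt_start=float(seg_rt[0]),
                rt_end=float(seg_rt[-1]),
                trace_rt=seg_rt.copy(),
                trace_intensity=seg_int.copy(),
            )
        )


def deisotope(features: Sequence[Feature], cfg: DetectionConfig) -> List[Feature]:
    """13C isotope filter: collapse series spaced by 1.00335/z (monotonically
    decreasing intensity, co-eluting) to their most intense member."""
    feats = sorted(features, key=lambda f: f.mz)
    satellite = [False] * len(feats)
    # satellites still anchor the next chain member (M+1 -> M+2 -> ...)
    for i, f in enumerate(feats):
        for z in range(1, cfg.max_charge + 1):
            delta = ISOTOPE_DELTA / z
            tol = cfg.iso_window(f.mz)
            for k in range(i + 1, len(feats)):
                g = feats[k]
                if g.mz - f.mz > delta + tol:
                    break
                if (abs(g.mz - f.mz - delta) <= tol
                        and abs(g.rt - f.rt) <= cfg.iso_rt_tol
                        and g.height < f.height):
                    satellite[k] = True
    return [f for f, s in zip(feats, satellite) if not s]


def detect_features(run: MSRun, level: int, cfg: DetectionConfig) -> List[Feature]:
    """Full single-sample chain at one level: EICs -> peaks -> de-isotoping."""
    feats: List[Feature] = []
    for eic in build_eics(run, level, cfg):
        feats.extend(resolve_peaks(eic, cfg, sample_id=run.sample_id))
    return deisotope(feats, cfg)


# ---------------------------------------------------------------------------
# Alignment and gap filling
# ---------------------------------------------------------------------------


@dataclass
class AlignedRow:
    mz: float
    rt: float
    members: Dict[str, Feature] = field(default_factory=dict)

    def refresh(self) -> None:
        self.mz = float(np.mean([f.mz for f in self.members.values()]))
        self.rt = float(np.mean([f.rt for f in self.members.values()]))

    def intensity(self, sample_id: str) -> float:
        f = self.members.get(sample_id)
        return f.height if f is not None else 0.0


@dataclass
class AlignedTable:
    ms_level: int
    sample_ids: List[str]
    rows: List[AlignedRow]

    def intensity_matrix(self):
        import pandas as pd

        return pd.DataFrame(
            {sid: [row.intensity(sid) for row in self.rows] for sid in self.sample_ids},
            index=[f"{row.mz:.4f}@{row.rt:.3f}" for row in self.rows],
        )

    def to_frame(self):
        import pandas as pd

        data = {
            "mz": [round(r.mz, 4) for r in self.rows],
            "rt": [round(r.rt, 3) for r in self.rows],
        }
        for sid in self.sample_ids:
            data[f"height_{sid}"] = [r.intensity(sid) for r in self.rows]
            data[f"gapfilled_{sid}"] = [
                bool(r.members[sid].gap_filled) if sid in r.members else False
                for r in self.rows
            ]
        return pd.DataFrame(data)


def align(per_sample: Dict[str, Sequence[Feature]], cfg: DetectionConfig) -> AlignedTable:
    """Join-aligner-style greedy matching across samples.

    Samples are folded into a master list in input order.  Candidates within
    both the m/z and RT tolerances are scored
    ``mz_weight * (1 - |dmz|/mz_tol) + rt_weight * (1 - |drt|/rt_tol)``;
    the highest score wins, ties broken by smaller |dmz| then input order.
    Unmatched features open new rows.
    """
    if not per_sample:
        raise ValueError("need at least one sample to align")
    sample_ids = list(per_sample)
    level = None
    rows: List[AlignedRow] = []
    for sid in sample_ids:
        feats = list(per_sample[sid])
        if feats and level is None:
            level = feats[0].ms_level
        candidates: List[Tuple[float, float, int, int]] = []
        for fi, f in enumerate(feats):
            for ri, row in enumerate(rows):
                mz_tol = cfg.align_window(row.mz)
                dmz = abs(f.mz - row.mz)
                drt = abs(f.rt - row.rt)
                if dmz <= mz_tol and drt <= cfg.align_rt_tol:
                    score = (cfg.align_mz_weight * (1 - dmz / mz_tol)
                             + cfg.align_rt_weight * (1 - drt / cfg.align_rt_tol))
                    candidates.append((score, dmz, fi, ri))
        candidates.sort(key=lambda t: (-t[0], t[1], t[2], t[3]))
        used_f: set = set()
        used_r: set = set()
        for score, dmz, fi, ri in candidates:
            if fi in used_f or ri in used_r or sid in rows[ri].members:
                continue
            rows[ri].members[sid] = feats[fi]
            rows[ri].refresh()
            used_f.add(fi)
            used_r.add(ri)
        for fi, f in enumerate(feats):
            if fi not in used_f:
                rows.append(AlignedRow(f.mz, f.rt, {sid: f}))
    rows.sort(key=lambda r: (r.mz, r.rt))
    return AlignedTable(ms_level=level or 1, sample_ids=sample_ids, rows=rows)


def _is_unimodal(vals: np.ndarray, rel_tol: float) -> bool:
    apex = int(np.argmax(vals))
    for i in range(apex):
        if vals[i + 1] < vals[i] * (1 - rel_tol):
            return False
    for i in range(apex, vals.size - 1):
        if vals[i + 1] > vals[i] * (1 + rel_tol):
            return False
    return True


def gap_fill(table: AlignedTable, runs: Sequence[MSRun], cfg: DetectionConfig) -> AlignedTable:
    """Targeted re-integration of raw signal for empty aligned cells.

    For each missing (row, sample) cell, raw centroids within the row's m/z
    and RT gap-filling tolerances are collected; the cell is filled only if
    at least ``gapfill_min_scans`` contiguous scans form a unimodal profile
    (flank violations up to the relative intensity tolerance allowed).
    Filled features are flagged ``gap_filled``.
    """
    run_map = {r.sample_id: r for r in runs}
    # flat per-run centroid index at this level, sorted by m/z
    index: Dict[str, Tuple[np.ndarray, ...]] = {}
    for sid, run in run_map.items():
        specs = run.spectra_at_level(table.ms_level)
        mzs, rts, poss, ints = [], [], [], []
        for pos, s in enumerate(specs):
            mzs.append(s.mz)
            ints.append(s.intensity)
            rts.append(np.full(s.mz.size, s.rt))
            poss.append(np.full(s.mz.size, pos))
        mz = np.concatenate(mzs) if mzs else np.empty(0)
        order = np.argsort(mz, kind="stable")
        index[sid] = (
            mz[order],
            np.concatenate(rts)[order],
            np.concatenate(poss)[order].astype(int),
            np.concatenate(ints)[order],
        )
    for row in table.rows:
        for sid in table.sample_ids:
            if sid in row.members or sid not in index:
                continue
            mz, rt, pos, inten = index[sid]
            w = cfg.gapfill_window(row.mz)
            lo = np.searchsorted(mz, row.mz - w, side="left")
            hi = np.searchsorted(mz, row.mz + w, side="right")
            sel = slice(lo, hi)
            mask = np.abs(rt[sel] - row.rt) <= cfg.gapfill_rt_tol
            if not mask.any():
                continue
            cand_pos = pos[sel][mask]
            cand_int = inten[sel][mask]
            cand_rt = rt[sel][mask]
            cand_mz = mz[sel][mask]
            # per-scan best (most intense) candidate
            per_scan: Dict[int, Tuple[float, float, float]] = {}
            for p, ci, cr, cm in zip(cand_pos, cand_int, cand_rt, cand_mz):
                if p not in per_scan or ci > per_scan[p][0]:
                    per_scan[p] = (ci, cr, cm)
            scans = np.array(sorted(per_scan))
            # longest contiguous stretch
            best: Optional[np.ndarray] = None
            start = 0
            for k in range(1, scans.size + 1):
                if k == scans.size or scans[k] != scans[k - 1] + 1:
                    if best is None or k - start > best.size:
                        best = scans[start:k]
                    start = k
            if best is None or best.size < cfg.gapfill_min_scans:
                continue
            vals = np.array([per_scan[p][0] for p in best])
            if not _is_unimodal(vals, cfg.gapfill_intensity_tol):
                continue
            rts_ = np.array([per_scan[p][1] for p in best])
            mzs_ = np.array([per_scan[p][2] for p in best])
            apex = int(np.argmax(vals))
            row.members[sid] = Feature(
                sample_id=sid,
                ms_level=table.ms_level,
                mz=float(np.average(mzs_, weights=vals)),
                rt=float(rts_[apex]),
                height=float(vals[apex]),
                area=float(np.trapezoid(vals, rts_)),
                rt_start=float(rts_[0]),
                rt_end=float(rts_[-1]),
                trace_rt=rts_,
                trace_intensity=vals,
                gap_filled=True,
            )
    return table
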