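"""Synthetic DIA-run generator with ground truth.

Emulates the structure that matters for this pipeline: co-eluting Gaussian
precursor/fragment elution profiles split across alternating low-energy
(MS1) and high-energy (MS2) scans, an M+1 isotope satellite on the
precursor channel, per-point m/z jitter and a uniform noise floor.  Every
spiked glycoside carries its expected annotation strings, so end-to-end
recall and precision are measurable without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import chemcore
from .chemcore import (
    PROTON_MASS,
    C13_C12_DELTA,
    ETENOL_RESIDUE,
    PROPANEDIOL_RESIDUE,
    SugarLossDef,
)
from .dbio import CompoundRecord, MSRun, Spectrum

__all__ = [
    "SpikeSpec",
    "SimTruth",
    "simulate_run",
    "make_cohort",
    "cohort_compound_db",
    "truth_compare",
    "COHORT_AGLYCONES",
    "COHORT_SUGARS",
]


@dataclass
class SpikeSpec:
    """One spiked glycoside in one sample."""

    name: str                       # e.g. "Quercetin O-hexoside"
    aglycone: str
    aglycone_formula: str
    bond: str                       # "O" | "C"
    precursor_mz: float
    fragments: Tuple[Tuple[float, float], ...]  # (m/z, yield relative to precursor)
    rt: float                       # apex, minutes
    rt_sigma: float                 # minutes
    height: float
    sample_id: str
    n_carbons: int = 15

    def __post_init__(self) -> None:
        if self.height <= 0:
            raise ValueError(f"spike {self.name!r}: height must be positive")
        if self.rt_sigma <= 0:
            raise ValueError(f"spike {self.name!r}: rt_sigma must be positive")
        if any(y > 1 or y <= 0 for _, y in self.fragments):
            raise ValueError(f"spike {self.name!r}: fragment yields must be in (0, 1]")


@dataclass
class TruthCompound:
    """Cohort-level ground truth for one spiked glycoside."""

    name: str
    aglycone: str
    flavonoid_class: str
    bond: str
    neutral_mass: float
    precursor_mz: float
    rt: float
    expected_annotations: Tuple[str, ...]


@dataclass
class SimTruth:
    compounds: List[TruthCompound]
    spikes: List[SpikeSpec]
    seed: int
    noise_floor: float
    mz_jitter_ppm: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": [c.name for c in self.compounds],
                "aglycone": [c.aglycone for c in self.compounds],
                "class": [c.flavonoid_class for c in self.compounds],
                "bond": [c.bond for c in self.compounds],
                "neutral_mass": [round(c.neutral_mass, 4) for c in self.compounds],
                "precursor_mz": [round(c.precursor_mz, 4) for c in self.compounds],
                "rt": [round(c.rt, 3) for c in self.compounds],
                "expected": ["; ".join(c.expected_annotations) for c in self.compounds],
            }
        )


def simulate_run(
    specs: Sequence[SpikeSpec],
    run_length: float = 10.0,
    scan_rate: float = 10.0,
    noise_floor: float = 200.0,
    mz_jitter_ppm: float = 2.0,
    seed: int = 0,
    noise_peaks_per_scan: int = 10,
    mz_range: Tuple[float, float] = (50.0, 1000.0),
    sample_id: str = "sample",
    isotope_abundance_per_c: float = 0.011,
) -> MSRun:
    """Simulate one DIA run with alternating MS1/MS2 scans.

    ``scan_rate`` is per channel (Hz); each acquisition cycle emits one
    low-energy scan and, half a cycle later, one high-energy scan.  A spike
    contributes a Gaussian elution profile to the MS1 channel (plus an M+1
    satellite at +1.0033 Da with relative abundance ~1.1% per carbon) and
    its fragments to the MS2 channel with the identical profile scaled by
    their yields.  Noise centroids are drawn uniformly in m/z at intensities
    scattered around the floor.  Deterministic for a fixed seed.
    """
    for s in specs:
        if not (0 <= s.rt <= run_length):
            raise ValueError(f"spike {s.name!r}: rt outside the run")
    rng = np.random.default_rng(seed)
    n_cycles = int(round(run_length * 60.0 * scan_rate))
    cycle_min = 1.0 / (scan_rate * 60.0)

    prec_mz = np.array([s.precursor_mz for s in specs])
    heights = np.array([s.height for s in specs])
    rts = np.array([s.rt for s in specs])
    sigmas = np.array([s.rt_sigma for s in specs])
    iso_frac = np.array([isotope_abundance_per_c * s.n_carbons for s in specs])
    frag_spike: List[int] = []
    frag_mz: List[float] = []
    frag_yield: List[float] = []
    for i, s in enumerate(specs):
        for fmz, fy in s.fragments:
            frag_spike.append(i)
            frag_mz.append(fmz)
            frag_yield.append(fy)
    frag_spike_a = np.array(frag_spike, dtype=int)
    frag_mz_a = np.array(frag_mz)
    frag_yield_a = np.array(frag_yield)

    spectra: List[Spectrum] = []

    def emit(index: int, rt: float, level: int, sig_mz: np.ndarray, sig_int: np.ndarray) -> None:
        noise_mz = rng.uniform(mz_range[0], mz_range[1], noise_peaks_per_scan)
        noise_int = noise_floor * rng.uniform(0.25, 3.5, noise_peaks_per_scan)
        mz = np.concatenate([sig_mz, noise_mz])
        inten = np.concatenate([sig_int, noise_int])
        if mz.size:
            mz = mz * (1.0 + rng.normal(0.0, mz_jitter_ppm * 1e-6, mz.size))
            order = np.argsort(mz, kind="stable")
            mz, inten = mz[order], inten[order]
            # merge pathological exact ties to keep m/z strictly increasing
            if mz.size > 1 and np.any(np.diff(mz) <= 0):
                umz, inv = np.unique(mz, return_inverse=True)
                uint = np.zeros(umz.size)
                np.add.at(uint, inv, inten)
                mz, inten = umz, uint
        spectra.append(Spectrum(index, rt, level, "negative", mz, inten))

    for c in range(n_cycles):
        t1 = c * cycle_min
        t2 = t1 + 0.5 * cycle_min
        if specs:
            amp1 = heights * np.exp(-0.5 * ((t1 - rts) / sigmas) ** 2)
            act = amp1 >= 1.0
            mz1 = np.concatenate([prec_mz[act], prec_mz[act] + C13_C12_DELTA])
            int1 = np.concatenate([amp1[act], amp1[act] * iso_frac[act]])
            amp2 = heights * np.exp(-0.5 * ((t2 - rts) / sigmas) ** 2)
            famp = amp2[frag_spike_a] * frag_yield_a
            fact = famp >= 1.0
            mz2, int2 = frag_mz_a[fact], famp[fact]
        else:
            mz1 = int1 = mz2 = int2 = np.empty(0)
        emit(2 * c, t1, 1, mz1, int1)
        emit(2 * c + 1, t2, 2, mz2, int2)

    return MSRun(sample_id=sample_id, spectra=spectra,
                 run_length=run_length, polarity="negative")


# ---------------------------------------------------------------------------
# Cohort construction
# ---------------------------------------------------------------------------

#: Mass-distinct aglycone backbones used for synthetic cohorts
#: (formula-level annotation cannot separate exact-mass isomers).
COHORT_AGLYCONES: Tuple[Tuple[str, str, str], ...] = (
    ("Kaempferol", "C15H10O6", "flavonol"),
    ("Quercetin", "C15H10O7", "flavonol"),
    ("Apigenin", "C15H10O5", "flavone"),
    ("Myricetin", "C15H10O8", "flavonol"),
    ("Naringenin", "C15H12O5", "flavanone"),
    ("Taxifolin", "C15H12O7", "flavanonol"),
    ("Catechin", "C15H14O6", "flavan-3-ol"),
)

_SUGARS = {s.name: s for s in chemcore.DEFAULT_SUGAR_LOSSES}

#: (label, bond, attached-glycosyl mass, MS2 fragment residues with yields,
#: expected sugar-dictionary names per fragment)
COHORT_SUGARS: Tuple[Dict, ...] = (
    {
        "label": "O-hexoside",
        "bond": "O",
        "attached": _SUGARS["O-hexoside"].mass,
        "carbons": 6,
    },
    {
        "label": "O-pentoside",
        "bond": "O",
        "attached": _SUGARS["O-pentoside"].mass,
        "carbons": 5,
    },
    {
        "label": "O-deoxyhexoside",
        "bond": "O",
        "attached": _SUGARS["O-deoxyhexoside"].mass,
        "carbons": 6,
    },
    {
        "label": "O-coumaroyl-deoxyhexoside",
        "bond": "O",
        "attached": _SUGARS["O-coumaroyl-deoxyhexoside"].mass,
        "carbons": 15,
    },
    {
        # one C-bound hexose; fragments retain etenol (loss 120) or C3H4O2 (loss 90)
        "label": "C-hexoside",
        "bond": "C",
        "attached": _SUGARS["O-hexoside"].mass,
        "carbons": 6,
        "residues": ((ETENOL_RESIDUE, 0.5), (PROPANEDIOL_RESIDUE, 0.35)),
        "expected": ("C-hexoside", "C-hexoside or C-pentoside"),
    },
    {
        # schaftoside-type: one C-hexose + one C-pentose, di-etenol fragment
        "label": "C-hexoside-C-pentoside",
        "bond": "C",
        "attached": _SUGARS["O-hexoside"].mass + _SUGARS["O-pentoside"].mass,
        "carbons": 11,
        "residues": ((2 * ETENOL_RESIDUE, 0.5),
                     (ETENOL_RESIDUE + PROPANEDIOL_RESIDUE, 0.3)),
        "expected": ("di-C-hexoside or C-hexoside-C-pentoside",
                     "di-C-pentoside or C-hexoside-C-pentoside (-60-120)"),
    },
)

#: Relative MS2 yields of the O-cleavage fragments.
O_HETEROLYTIC_YIELD = 0.6
O_HOMOLYTIC_YIELD = 0.3


def _build_compound(aglycone, formula, fclass, sugar_def, rt, rng) -> Tuple[TruthCompound, dict]:
    agly_mass = chemcore.formula_mass(formula)
    neutral = agly_mass + sugar_def["attached"]
    precursor = neutral - PROTON_MASS
    base = agly_mass - PROTON_MASS
    if sugar_def["bond"] == "O":
        fragments = ((base, O_HETEROLYTIC_YIELD),
                     (base - chemcore.H_ATOM_MASS, O_HOMOLYTIC_YIELD))
        expected = (f"{aglycone} {sugar_def['label']}",)
    else:
        fragments = tuple((base + res, y) for res, y in sugar_def["residues"])
        expected = tuple(f"{aglycone} {name}" for name in sugar_def["expected"])
    comp = chemcore.parse_formula(formula)
    n_c = comp.get("C", 0) + sugar_def["carbons"]
    name = f"{aglycone} {sugar_def['label']}"
    truth = TruthCompound(
        name=name, aglycone=aglycone, flavonoid_class=fclass,
        bond=sugar_def["bond"], neutral_mass=neutral, precursor_mz=precursor,
        rt=rt, expected_annotations=expected,
    )
    payload = {"fragments": fragments, "n_carbons": n_c, "formula": formula}
    return truth, payload


def make_cohort(
    n_spikes: int = 20,
    n_samples: int = 3,
    seed: int = 0,
    run_length: float = 10.0,
    scan_rate: float = 10.0,
    rt_window: Tuple[float, float] = (1.5, 6.0),
    rt_sigma: float = 0.02,
    height_range: Tuple[float, float] = (2e4, 2e5),
    noise_floor: float = 200.0,
    mz_jitter_ppm: float = 2.0,
    noise_peaks_per_scan: int = 10,
) -> Tuple[List[MSRun], SimTruth]:
    """Build a multi-sample synthetic cohort of spiked glycosides.

    Spikes are drawn without replacement from the aglycone x sugar grid
    (distinct compounds; the rare exact-mass isomer pairs, e.g.
    kaempferol-O-hexoside vs quercetin-O-deoxyhexoside, are separated
    chromatographically), placed on a jittered RT grid
    across the elution window so no two apexes fall within one alignment RT
    tolerance, and spiked into every sample with per-sample height
    variation.  Returns the runs (one per sample) and the ground truth.
    """
    rng = np.random.default_rng(seed)
    combos = [
        (agly, formula, fclass, sugar)
        for agly, formula, fclass in COHORT_AGLYCONES
        for sugar in COHORT_SUGARS
    ]
    if n_spikes > len(combos):
        raise ValueError(f"at most {len(combos)} distinct spikes available")
    order = rng.permutation(len(combos))
    chosen = [combos[i] for i in order[:n_spikes]]

    lo, hi = rt_window
    grid = np.linspace(lo, hi, n_spikes)
    spacing = (hi - lo) / max(n_spikes - 1, 1)
    rts = grid + rng.uniform(-0.2, 0.2, n_spikes) * min(spacing / 2 - 0.05, 0.1)
    rts = np.clip(rts, lo, hi)

    compounds: List[TruthCompound] = []
    payloads: List[dict] = []
    for (agly, formula, fclass, sugar), rt in zip(chosen, rts):
        truth, payload = _build_compound(agly, formula, fclass, sugar, float(rt), rng)
        compounds.append(truth)
        payloads.append(payload)

    sample_ids = [f"S{i + 1}" for i in range(n_samples)]
    spikes: List[SpikeSpec] = []
    runs: List[MSRun] = []
    for si, sid in enumerate(sample_ids):
        sample_spikes = []
        for comp, payload in zip(compounds, payloads):
            height = float(rng.uniform(*height_range))
            sample_spikes.append(
                SpikeSpec(
                    name=comp.name,
                    aglycone=comp.aglycone,
                    aglycone_formula=payload["formula"],
                    bond=comp.bond,
                    precursor_mz=comp.precursor_mz,
                    fragments=payload["fragments"],
                    rt=comp.rt,
                    rt_sigma=rt_sigma,
                    height=height,
                    sample_id=sid,
                    n_carbons=payload["n_carbons"],
                )
            )
        spikes.extend(sample_spikes)
        runs.append(
            simulate_run(
                sample_spikes,
                run_length=run_length,
                scan_rate=scan_rate,
                noise_floor=noise_floor,
                mz_jitter_ppm=mz_jitter_ppm,
                seed=int(rng.integers(0, 2**31 - 1)),
                noise_peaks_per_scan=noise_peaks_per_scan,
                sample_id=sid,
            )
        )
    truth = SimTruth(
        compounds=compounds, spikes=spikes, seed=seed,
        noise_floor=noise_floor, mz_jitter_ppm=mz_jitter_ppm,
    )
    return runs, truth


def cohort_compound_db(truth: SimTruth) -> List[CompoundRecord]:
    """MS1 compound records (neutral-mass basis, RT wildcard) for a cohort."""
    return [
        CompoundRecord(
            name=c.name,
            mass=c.neutral_mass,
            formula="",
            rt=None,
            flavonoid_class=c.flavonoid_class,
            source_db="synthetic_cohort",
            rt_wildcard=True,
        )
        for c in truth.compounds
    ]


def truth_compare(
    truth: SimTruth,
    annotations: Sequence,
    mz_tol: float = 0.01,
    rt_tol: float = 0.06,
) -> Dict:
    """Score pipeline glycoside annotations against the ground truth.

    An annotation matches a spiked compound when its precursor m/z and RT
    fall within the tolerances; it is *correct* when its report string is
    one of the compound's expected annotation strings.  Recall is the
    fraction of compounds with at least one correct annotation; precision
    the fraction of annotations that are correct.
    """
    matched: Dict[str, List[str]] = {c.name: [] for c in truth.compounds}
    n_correct = 0
    details = []
    for ann in annotations:
        mz = ann.pair.ms1_mz
        rt = ann.pair.rt
        correct = False
        for comp in truth.compounds:
            if abs(mz - comp.precursor_mz) <= mz_tol and abs(rt - comp.rt) <= rt_tol:
                if ann.report in comp.expected_annotations:
                    matched[comp.name].append(ann.report)
                    correct = True
                break
        n_correct += correct
        details.append((round(mz, 4), round(rt, 3), ann.report, correct))
    hit = [name for name, anns in matched.items() if anns]
    missed = [name for name, anns in matched.items() if not anns]
    n_total = len(annotations)
    return {
        "n_spiked": len(truth.compounds),
        "n_annotations": n_total,
        "recall": len(hit) / len(truth.compounds) if truth.compounds else 0.0,
        "precision": n_correct / n_total if n_total else 0.0,
        "matched": hit,
        "missed": missed,
        "details": details,
    }
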