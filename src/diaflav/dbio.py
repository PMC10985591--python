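"""Readers and writers: DIA mzML runs, compound/fragment database CSVs and
feature/annotation tables.

The DIA channel convention follows the common Waters-conversion layout: the
low-energy (precursor) function is stored as MS level 1 and the high-energy
all-ion function as MS level 2, with no precursor-isolation metadata on the
level-2 scans.  Retention times are minutes everywhere.

mzML parsing is implemented directly on the XML (the standard subset:
``cvParam`` metadata plus base64 ``binaryDataArray`` payloads, 32/64-bit
float, optionally zlib-compressed); writing emits a minimal
standard-conformant mzML 1.1.0 document (64-bit little-endian arrays,
base64, no compression) so that synthetic runs round-trip losslessly.
"""

from __future__ import annotations

import base64
import struct
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence
from xml.etree import ElementTree
from xml.sax.saxutils import escape

import numpy as np
import pandas as pd

from . import chemcore

__all__ = [
    "Spectrum",
    "MSRun",
    "CompoundRecord",
    "read_mzml",
    "write_mzml",
    "read_compound_db",
    "write_compound_db",
    "read_fragment_db",
    "write_fragment_db",
    "DEFAULT_COLUMN_MAP",
]


@dataclass
class Spectrum:
    """One centroided scan."""

    index: int
    rt: float  # minutes
    ms_level: int
    polarity: str  # "positive" | "negative"
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("m/z and intensity arrays must have equal length")
        if self.mz.size > 1 and not np.all(np.diff(self.mz) > 0):
            raise ValueError(f"spectrum {self.index}: m/z must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError(f"spectrum {self.index}: negative intensity")
        if self.rt < 0:
            raise ValueError(f"spectrum {self.index}: negative retention time")


@dataclass
class MSRun:
    """An ordered DIA acquisition for one sample."""

    sample_id: str
    spectra: List[Spectrum]
    run_length: float = 10.0  # minutes
    polarity: str = "negative"

    def __post_init__(self) -> None:
        rts = [s.rt for s in self.spectra]
        if any(b < a for a, b in zip(rts, rts[1:])):
            raise ValueError("retention time must be non-decreasing with scan index")

    def levels(self) -> set:
        return {s.ms_level for s in self.spectra}

    def spectra_at_level(self, level: int) -> List[Spectrum]:
        out = [s for s in self.spectra if s.ms_level == level]
        if not out:
            raise ValueError(f"run {self.sample_id!r} has no MS level {level} scans")
        return out


@dataclass
class CompoundRecord:
    """One MS1 database entry (neutral monoisotopic mass basis)."""

    name: str
    mass: float
    formula: str = ""
    rt: Optional[float] = None  # minutes; None = wildcard (full run)
    flavonoid_class: str = "other"
    source_db: str = ""
    rt_wildcard: bool = False

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError(f"compound {self.name!r}: mass must be positive")


# ---------------------------------------------------------------------------
# mzML
# ---------------------------------------------------------------------------


def _local(tag: str) -> str:
    """Strip the XML namespace from a tag name."""
    return tag.rsplit("}", 1)[-1]


def _decode_binary_array(bda: ElementTree.Element) -> tuple:
    """Decode one ``binaryDataArray``: returns (kind, values) where kind is
    'mz', 'intensity' or None for other array types."""
    dtype = "<d"
    compressed = False
    kind = None
    payload = b""
    for child in bda.iter():
        tag = _local(child.tag)
        if tag == "cvParam":
            acc = child.get("accession", "")
            if acc == "MS:1000521":
                dtype = "<f"
            elif acc == "MS:1000523":
                dtype = "<d"
            elif acc == "MS:1000574":
                compressed = True
            elif acc == "MS:1000514":
                kind = "mz"
            elif acc == "MS:1000515":
                kind = "intensity"
        elif tag == "binary" and child.text:
            payload = base64.b64decode(child.text.strip())
    if compressed:
        payload = zlib.decompress(payload)
    values = np.frombuffer(payload, dtype=np.dtype(dtype)).astype(float)
    return kind, values


def _parse_spectrum(elem: ElementTree.Element, fallback_index: int) -> Spectrum:
    ms_level = 1
    polarity = "negative"
    rt = 0.0
    profile = False
    centroid = False
    mz = np.empty(0)
    intensity = np.empty(0)
    for child in elem.iter():
        if _local(child.tag) == "cvParam":
            acc = child.get("accession", "")
            if acc == "MS:1000511":
                ms_level = int(child.get("value", "1"))
            elif acc == "MS:1000129":
                polarity = "negative"
            elif acc == "MS:1000130":
                polarity = "positive"
            elif acc == "MS:1000128":
                profile = True
            elif acc == "MS:1000127":
                centroid = True
            elif acc == "MS:1000016":
                rt = float(child.get("value", "0"))
                if child.get("unitName", "minute") in ("second", "seconds"):
                    rt /= 60.0
    for child in elem.iter():
        if _local(child.tag) == "binaryDataArray":
            kind, values = _decode_binary_array(child)
            if kind == "mz":
                mz = values
            elif kind == "intensity":
                intensity = values
    if profile and not centroid:
        raise ValueError(
            f"spectrum {elem.get('id', fallback_index)} is profile-mode; "
            "centroid the data first"
        )
    index = fallback_index
    try:
        index = int(elem.get("index", fallback_index))
    except (TypeError, ValueError):
        pass
    return Spectrum(
        index=index, rt=rt, ms_level=ms_level, polarity=polarity,
        mz=mz, intensity=intensity,
    )


def read_mzml(path, sample_id: Optional[str] = None, run_length: Optional[float] = None) -> MSRun:
    """Read a centroided DIA mzML file into an :class:`MSRun`.

    Retention times are converted to minutes.  A run carrying only MS level 1
    is accepted with a warning — downstream MS2-dependent stages will refuse
    it themselves.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    spectra: List[Spectrum] = []
    try:
        context = ElementTree.iterparse(str(path), events=("end",))
        for _, elem in context:
            if _local(elem.tag) == "spectrum":
                spectra.append(_parse_spectrum(elem, len(spectra)))
                elem.clear()
    except ElementTree.ParseError as exc:
        raise ValueError(f"{path.name}: malformed mzML ({exc})") from exc
    if not spectra:
        raise ValueError(f"{path.name}: no spectra found")
    levels = {s.ms_level for s in spectra}
    if 2 not in levels:
        warnings.warn(
            f"{path.name}: only MS level(s) {sorted(levels)} present; "
            "MS2-dependent stages will not run",
            stacklevel=2,
        )
    length = run_length if run_length is not None else max(s.rt for s in spectra)
    return MSRun(
        sample_id=sample_id or path.stem,
        spectra=spectra,
        run_length=length,
        polarity=spectra[0].polarity,
    )


def _b64(arr: np.ndarray) -> str:
    return base64.b64encode(struct.pack(f"<{arr.size}d", *arr.astype(float))).decode()


_CV = '<cvParam cvRef="MS" accession="{acc}" name="{name}"{extra}/>'


def _cv(acc: str, name: str, value: Optional[str] = None, unit: Optional[Sequence[str]] = None) -> str:
    extra = ""
    if value is not None:
        extra += f' value="{escape(str(value))}"'
    if unit is not None:
        extra += (
            f' unitCvRef="{unit[0]}" unitAccession="{unit[1]}" unitName="{unit[2]}"'
        )
    return _CV.format(acc=acc, name=escape(name), extra=extra)


def write_mzml(run: MSRun, path) -> None:
    """Write an :class:`MSRun` as minimal mzML 1.1.0.

    ``read_mzml(write_mzml(run))`` is the identity on (RT, MS level,
    polarity, m/z, intensity); arrays are stored uncompressed as 64-bit
    little-endian floats so the round trip is bitwise.
    """
    path = Path(path)
    lines: List[str] = []
    w = lines.append
    w('<?xml version="1.0" encoding="utf-8"?>')
    w(
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0" '
        f'id="{escape(run.sample_id)}">'
    )
    w('<cvList count="2">')
    w(
        '<cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" '
        'URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>'
    )
    w(
        '<cv id="UO" fullName="Unit Ontology" '
        'URI="https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo"/>'
    )
    w("</cvList>")
    w('<fileDescription><fileContent>')
    w(_cv("MS:1000579", "MS1 spectrum"))
    w(_cv("MS:1000580", "MSn spectrum"))
    w("</fileContent></fileDescription>")
    w('<softwareList count="1"><software id="diaflav" version="0.1.0"/></softwareList>')
    w(
        '<instrumentConfigurationList count="1">'
        '<instrumentConfiguration id="IC1"/></instrumentConfigurationList>'
    )
    w(
        '<dataProcessingList count="1"><dataProcessing id="dp1">'
        '<processingMethod order="1" softwareRef="diaflav">'
        + _cv("MS:1000544", "Conversion to mzML")
        + "</processingMethod></dataProcessing></dataProcessingList>"
    )
    w(f'<run id="{escape(run.sample_id)}" defaultInstrumentConfigurationRef="IC1">')
    w(f'<spectrumList count="{len(run.spectra)}" defaultDataProcessingRef="dp1">')
    for i, spec in enumerate(run.spectra):
        mz_b, int_b = _b64(spec.mz), _b64(spec.intensity)
        w(
            f'<spectrum index="{i}" id="scan={spec.index}" '
            f'defaultArrayLength="{spec.mz.size}">'
        )
        w(_cv("MS:1000511", "ms level", spec.ms_level))
        w(_cv("MS:1000127", "centroid spectrum"))
        if spec.polarity == "negative":
            w(_cv("MS:1000129", "negative scan"))
        else:
            w(_cv("MS:1000130", "positive scan"))
        w('<scanList count="1">')
        w(_cv("MS:1000795", "no combination"))
        w("<scan>")
        w(
            _cv(
                "MS:1000016",
                "scan start time",
                repr(spec.rt),
                ("UO", "UO:0000031", "minute"),
            )
        )
        w("</scan></scanList>")
        w('<binaryDataArrayList count="2">')
        for acc, name, data in (
            ("MS:1000514", "m/z array", mz_b),
            ("MS:1000515", "intensity array", int_b),
        ):
            w(f'<binaryDataArray encodedLength="{len(data)}">')
            w(_cv("MS:1000523", "64-bit float"))
            w(_cv("MS:1000576", "no compression"))
            w(_cv(acc, name))
            w(f"<binary>{data}</binary>")
            w("</binaryDataArray>")
        w("</binaryDataArrayList>")
        w("</spectrum>")
    w("</spectrumList></run></mzML>")
    path.write_text("\n".join(lines), encoding="utf-8")


# ---------------------------------------------------------------------------
# Compound / fragment database CSVs
# ---------------------------------------------------------------------------

#: Column-name mapping for database CSVs; the reader requires the exact
#: configured header names, mirroring how local-DB search modules are set up.
DEFAULT_COLUMN_MAP: Dict[str, str] = {
    "name": "name",
    "mass": "neutral_mass",
    "formula": "formula",
    "rt": "rt",
    "class": "class",
}


def read_compound_db(
    path,
    column_map: Optional[Dict[str, str]] = None,
    run_length: Optional[float] = None,
    source_db: str = "",
    mass_check_ppm: float = 5.0,
) -> List[CompoundRecord]:
    """Read an MS1 compound database CSV.

    ``column_map`` maps the roles name/mass/formula/rt/class to the actual
    CSV headers.  A record whose formula disagrees with its stated mass by
    more than ``mass_check_ppm`` is rejected with its row number.  An RT
    equal to ``run_length`` (the total chromatographic time) is the database
    convention for "any RT" and sets the wildcard flag.
    """
    cmap = dict(DEFAULT_COLUMN_MAP, **(column_map or {}))
    df = pd.read_csv(path)
    for role in ("name", "mass"):
        if cmap[role] not in df.columns:
            raise ValueError(
                f"{Path(path).name}: mapped column {cmap[role]!r} (role {role!r}) missing"
            )
    records: List[CompoundRecord] = []
    for row_no, (_, row) in enumerate(df.iterrows(), start=2):
        name = str(row[cmap["name"]])
        try:
            mass = float(row[cmap["mass"]])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{Path(path).name} row {row_no}: unparseable mass") from exc
        formula = str(row.get(cmap["formula"], "") or "")
        if formula and formula.lower() != "nan":
            ref = chemcore.formula_mass(formula)
            if abs(chemcore.ppm_error(mass, ref)) > mass_check_ppm:
                raise ValueError(
                    f"{Path(path).name} row {row_no} ({name}): stated mass {mass} "
                    f"disagrees with formula {formula} ({ref:.4f}) by "
                    f"> {mass_check_ppm} ppm"
                )
        else:
            formula = ""
        rt_raw = row.get(cmap["rt"])
        rt = None if rt_raw is None or pd.isna(rt_raw) else float(rt_raw)
        wildcard = rt is None or (
            run_length is not None and abs(rt - run_length) < 1e-9
        )
        records.append(
            CompoundRecord(
                name=name,
                mass=mass,
                formula=formula,
                rt=rt,
                flavonoid_class=str(row.get(cmap["class"], "other") or "other"),
                source_db=source_db or Path(path).stem,
                rt_wildcard=wildcard,
            )
        )
    return records


def write_compound_db(records: Sequence[CompoundRecord], path,
                      column_map: Optional[Dict[str, str]] = None) -> None:
    """Write compound records in the dialect read back by
    :func:`read_compound_db`."""
    cmap = dict(DEFAULT_COLUMN_MAP, **(column_map or {}))
    pd.DataFrame(
        {
            cmap["name"]: [r.name for r in records],
            cmap["mass"]: [round(r.mass, 4) for r in records],
            cmap["formula"]: [r.formula for r in records],
            cmap["rt"]: [r.rt for r in records],
            cmap["class"]: [r.flavonoid_class for r in records],
        }
    ).to_csv(path, index=False)


_FRAG_COLUMNS = ("aglycone", "fragment", "mz", "rt", "cleavage", "residue_mass")


def write_fragment_db(
    records: Sequence[chemcore.FragmentRecord], path, run_length: float = 10.0
) -> None:
    """Write an MS2 aglycone-fragment database CSV.

    m/z values are on the [M - H]- basis; the RT column holds the total
    chromatographic time (the wildcard convention).
    """
    pd.DataFrame(
        {
            "aglycone": [r.aglycone for r in records],
            "fragment": [r.label for r in records],
            "mz": [round(r.mz, 4) for r in records],
            "rt": [run_length for _ in records],
            "cleavage": [r.cleavage for r in records],
            "residue_mass": [round(r.residue_mass, 4) for r in records],
        },
        columns=list(_FRAG_COLUMNS),
    ).to_csv(path, index=False)


def read_fragment_db(path) -> List[chemcore.FragmentRecord]:
    """Read back a fragment database written by :func:`write_fragment_db`."""
    df = pd.read_csv(path)
    missing = [c for c in ("fragment", "mz") if c not in df.columns]
    if missing:
        raise ValueError(f"{Path(path).name}: missing column(s) {missing}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            chemcore.FragmentRecord(
                aglycone=str(getattr(row, "aglycone", row.fragment)),
                label=str(row.fragment),
                mz=float(row.mz),
                cleavage=str(getattr(row, "cleavage", "heterolytic-O")),
                residue_mass=float(getattr(row, "residue_mass", 0.0)),
            )
        )
    return out
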