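"""Readers and writers for the package's tabular and spectra formats.

Matrices, peptide/glycan databases, annotations, and survival tables are
tab-separated UTF-8 text with '.' decimals and empty cells for missing
values. Spectra are read either from centroided mzML (via pyteomics) or
from the internal JSON-lines format (one spectrum object per line); the
simulator and pipeline write JSON-lines.
"""

from __future__ import annotations

import json
import logging
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from glycotyper.chem import GlycanComposition, GlycositePeptide
from glycotyper.ident import GlycoPSM, Spectrum

logger = logging.getLogger(__name__)

__all__ = [
    "load_glycan_db",
    "write_glycan_db",
    "load_enzyme_panel",
    "read_peptide_db",
    "write_peptide_db",
    "read_matrix",
    "write_matrix",
    "read_spectra",
    "write_spectra_jsonl",
    "read_psm_table",
    "write_psm_table",
]

_REPORTER_CHANNELS = {"114": 114.1112, "115": 115.1083, "116": 116.1116, "117": 117.1150}


def load_glycan_db(path: str | Path | None = None) -> list[GlycanComposition]:
    """Glycan composition database from TSV (hex, hexnac, fuc, neuac).

    With no path, the packaged toy database (~40 compositions spanning all
    five glycan-type labels) is returned.
    """
    if path is None:
        source = resources.files("glycotyper.data").joinpath("glycans.tsv")
        with resources.as_file(source) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    return [
        GlycanComposition(int(r.hex), int(r.hexnac), int(r.fuc), int(r.neuac))
        for r in df.itertuples(index=False)
    ]


def write_glycan_db(glycans: Iterable[GlycanComposition], path: str | Path) -> None:
    rows = [g.as_tuple() for g in glycans]
    pd.DataFrame(rows, columns=["hex", "hexnac", "fuc", "neuac"]).to_csv(
        path, sep="\t", index=False
    )


def load_enzyme_panel(path: str | Path | None = None) -> pd.DataFrame:
    """The glycoenzyme panel: gene, role, target glycan type, default sign."""
    if path is None:
        source = resources.files("glycotyper.data").joinpath("enzymes.tsv")
        with resources.as_file(source) as p:
            return pd.read_csv(p, sep="\t", index_col="gene")
    return pd.read_csv(path, sep="\t", index_col="gene")


def read_peptide_db(path: str | Path) -> list[GlycositePeptide]:
    """Peptide database TSV: protein_id, sequence, glycosite_index (0-based)."""
    df = pd.read_csv(path, sep="\t")
    return [
        GlycositePeptide(
            sequence=str(r.sequence),
            glycosite_index=int(r.glycosite_index),
            protein_id=str(r.protein_id),
        )
        for r in df.itertuples(index=False)
    ]


def write_peptide_db(peptides: Iterable[GlycositePeptide], path: str | Path) -> None:
    pd.DataFrame(
        [(p.protein_id, p.sequence, p.glycosite_index) for p in peptides],
        columns=["protein_id", "sequence", "glycosite_index"],
    ).to_csv(path, sep="\t", index=False)


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Abundance matrix TSV: first column feature_id, then one column per sample."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    out = matrix.copy()
    out.index.name = out.index.name or "feature_id"
    out.to_csv(path, sep="\t", na_rep="")


# ---------------------------------------------------------------------------
# Spectra


def _spectrum_to_json(s: Spectrum) -> dict:
    return {
        "spectrum_id": s.spectrum_id,
        "precursor_mz": s.precursor_mz,
        "precursor_charge": s.precursor_charge,
        "mz": [round(float(x), 6) for x in s.mz],
        "intensity": [round(float(x), 4) for x in s.intensity],
        "reporter_intensities": {k: round(float(v), 4) for k, v in s.reporter_intensities.items()},
    }


def write_spectra_jsonl(spectra: Iterable[Spectrum], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in spectra:
            fh.write(json.dumps(_spectrum_to_json(s), sort_keys=True) + "\n")


def _read_spectra_jsonl(path: Path) -> list[Spectrum]:
    spectra: list[Spectrum] = []
    n_bad = 0
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            try:
                d = json.loads(line)
                spectra.append(
                    Spectrum(
                        spectrum_id=str(d["spectrum_id"]),
                        precursor_mz=float(d["precursor_mz"]),
                        precursor_charge=int(d["precursor_charge"]),
                        mz=np.asarray(d["mz"], dtype=float),
                        intensity=np.asarray(d["intensity"], dtype=float),
                        reporter_intensities={
                            str(k): float(v)
                            for k, v in d.get("reporter_intensities", {}).items()
                        },
                    )
                )
            except (KeyError, ValueError, json.JSONDecodeError) as exc:
                n_bad += 1
                logger.warning("skipping malformed spectrum at line %d: %s", line_no, exc)
    if n_bad:
        logger.warning("%d malformed record(s) skipped from %s", n_bad, path)
    if not spectra:
        logger.warning("no spectra read from %s", path)
    return spectra


def _reporters_from_peaks(mz: np.ndarray, intensity: np.ndarray) -> dict[str, float]:
    out = {}
    for channel, target in _REPORTER_CHANNELS.items():
        window = np.abs(mz - target) <= 0.01
        out[channel] = float(intensity[window].sum()) if window.any() else 0.0
    return out


def _decode_binary(elem, ns: str) -> np.ndarray:
    """Decode one mzML <binaryDataArray>: 32/64-bit floats, optional zlib."""
    import base64
    import zlib

    accessions = {
        cv.get("accession") for cv in elem.findall(f"{ns}cvParam")
    }
    text = elem.findtext(f"{ns}binary") or ""
    raw = base64.b64decode(text)
    if "MS:1000574" in accessions:  # zlib compression
        raw = zlib.decompress(raw)
    dtype = "<f4" if "MS:1000521" in accessions else "<f8"
    return np.frombuffer(raw, dtype=dtype).astype(float)


def _read_spectra_mzml(path: Path) -> list[Spectrum]:
    """Minimal centroided-mzML reader (lxml): MS2 spectra with precursor info.

    Covers the subset of mzML 1.1 that ProteoWizard-style centroided MS/MS
    exports use: cvParam-annotated binary m/z and intensity arrays (64- or
    32-bit, optionally zlib-compressed) and selected-ion precursor blocks.
    """
    from lxml import etree

    spectra: list[Spectrum] = []
    n_bad = 0
    tree = etree.parse(str(path))
    root = tree.getroot()
    ns = f"{{{root.nsmap.get(None)}}}" if root.nsmap.get(None) else ""
    for spec in root.iter(f"{ns}spectrum"):
        try:
            cv = {c.get("accession"): c.get("value") for c in spec.findall(f"{ns}cvParam")}
            ms_level = cv.get("MS:1000511")
            if ms_level is not None and int(ms_level) != 2:
                continue
            ion = spec.find(
                f"{ns}precursorList/{ns}precursor/{ns}selectedIonList/{ns}selectedIon"
            )
            if ion is None:
                continue
            ion_cv = {c.get("accession"): c.get("value") for c in ion.findall(f"{ns}cvParam")}
            arrays: dict[str, np.ndarray] = {}
            for arr in spec.iter(f"{ns}binaryDataArray"):
                acc = {c.get("accession") for c in arr.findall(f"{ns}cvParam")}
                if "MS:1000514" in acc:
                    arrays["mz"] = _decode_binary(arr, ns)
                elif "MS:1000515" in acc:
                    arrays["intensity"] = _decode_binary(arr, ns)
            mz = arrays["mz"]
            intensity = arrays["intensity"]
            spectra.append(
                Spectrum(
                    spectrum_id=str(spec.get("id")),
                    precursor_mz=float(ion_cv["MS:1000744"]),
                    precursor_charge=int(ion_cv.get("MS:1000041", 2)),
                    mz=mz,
                    intensity=intensity,
                    reporter_intensities=_reporters_from_peaks(mz, intensity),
                )
            )
        except (KeyError, ValueError, TypeError) as exc:
            n_bad += 1
            logger.warning("skipping malformed mzML spectrum: %s", exc)
    if n_bad:
        logger.warning("%d malformed spectrum(s) skipped from %s", n_bad, path)
    return spectra


def read_spectra(path: str | Path) -> list[Spectrum]:
    """Read centroided MS/MS spectra from mzML or the internal JSON-lines format."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".mzml":
        return _read_spectra_mzml(path)
    return _read_spectra_jsonl(path)


# ---------------------------------------------------------------------------
# PSM tables

_PSM_COLUMNS = [
    "spectrum_id", "protein_id", "sequence", "glycosite_index",
    "hex", "hexnac", "fuc", "neuac",
    "score", "n_matched", "intensity_fraction", "is_decoy", "q_value",
]


def write_psm_table(psms: Iterable[GlycoPSM], path: str | Path) -> None:
    rows = []
    for p in psms:
        rows.append(
            (
                p.spectrum_id, p.peptide.protein_id, p.peptide.sequence,
                p.peptide.glycosite_index,
                p.glycan.hex, p.glycan.hexnac, p.glycan.fuc, p.glycan.neuac,
                round(p.morpheus_score, 6), p.n_matched_fragments,
                round(p.matched_intensity_fraction, 6),
                int(p.is_decoy),
                "" if p.q_value is None else round(p.q_value, 6),
            )
        )
    pd.DataFrame(rows, columns=_PSM_COLUMNS).to_csv(path, sep="\t", index=False)


def read_psm_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
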