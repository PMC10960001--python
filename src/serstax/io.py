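"""Domain types and plain-text I/O.

A :class:`Spectrum` is the atomic unit: a strictly increasing Raman-shift axis
(cm^-1), one intensity per point, and free-form string metadata.  Spectrum
files are two-column delimited text with ``#``-prefixed header lines, the
common export format of Raman instruments and diffable under version control.

An :class:`AnalyteLabel` is the structured ground truth for one analyte:
its category (MPBA blank, monosaccharide, or cerebroside), hexose (glucose or
galactose), ceramide saturation (number of C=C bonds, 0 or 1) and acyl chain
length.  ``nomenclature()`` renders the conventional name, e.g. ``GalCer24:1``
for the galactocerebroside with a 24-carbon mono-unsaturated ceramide.

A :class:`SpectrumSet` bundles parallel spectra / labels / concentrations and
round-trips through a manifest CSV (columns ``file, category, hexose,
saturation, chain_length, concentration_M, replicate``).  Concentrations are
kept as decimal strings in the manifest so write -> read -> write is
byte-identical.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd

from .errors import (
    EmptySpectrumError,
    SpectrumParseError,
    ValidationError,
)

__all__ = [
    "Spectrum",
    "AnalyteLabel",
    "SpectrumSet",
    "CHAIN_LENGTHS",
    "CLASS_ORDER",
    "all_labels",
    "read_spectrum",
    "write_spectrum",
    "read_manifest",
    "write_manifest",
]

#: Ceramide acyl chain lengths covered by the study design.
CHAIN_LENGTHS = (8, 12, 16, 18, 24)

#: Canonical ordering of the 14 analyte classes (blank, 2 monosaccharides,
#: 5 glucocerebrosides, 6 galactocerebrosides).
CLASS_ORDER = (
    "MPBA blank",
    "glucose",
    "galactose",
    "GlcCer8",
    "GlcCer12",
    "GlcCer16",
    "GlcCer18",
    "GlcCer24:1",
    "GalCer8",
    "GalCer12",
    "GalCer16",
    "GalCer18",
    "GalCer24",
    "GalCer24:1",
)


@dataclass
class Spectrum:
    """One Raman/SERS spectrum.

    Parameters
    ----------
    wavenumbers
        Strictly increasing Raman shifts in cm^-1.
    intensities
        Intensities (arbitrary units), same length as ``wavenumbers``.
    meta
        Free-form string metadata (analyte id, concentration, replicate id,
        preprocessing state flags, ...).
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavenumbers.ndim != 1 or self.intensities.ndim != 1:
            raise ValidationError("spectrum axes must be one-dimensional")
        if self.wavenumbers.shape != self.intensities.shape:
            raise ValidationError(
                f"axis length mismatch: {self.wavenumbers.size} wavenumbers "
                f"vs {self.intensities.size} intensities"
            )
        if self.wavenumbers.size < 2:
            raise EmptySpectrumError("a spectrum needs at least two points")
        if not np.all(np.isfinite(self.wavenumbers)):
            raise ValidationError("non-finite wavenumber")
        if not np.all(np.isfinite(self.intensities)):
            raise ValidationError("non-finite intensity")
        dw = np.diff(self.wavenumbers)
        if np.any(dw <= 0):
            raise ValidationError("wavenumbers must be strictly increasing")

    @property
    def n_points(self) -> int:
        return int(self.wavenumbers.size)

    def copy(self) -> "Spectrum":
        return Spectrum(
            self.wavenumbers.copy(), self.intensities.copy(), dict(self.meta)
        )

    def with_intensities(self, y, **meta_updates) -> "Spectrum":
        """Return a new spectrum sharing this axis with new intensities."""
        meta = dict(self.meta)
        meta.update({k: str(v) for k, v in meta_updates.items()})
        return Spectrum(self.wavenumbers.copy(), np.asarray(y, float), meta)


_CATEGORIES = ("blank", "monosaccharide", "cerebroside")
_HEXOSES = ("glc", "gal")


@dataclass(frozen=True)
class AnalyteLabel:
    """Structured identity of an analyte.

    ``category`` is one of ``blank`` / ``monosaccharide`` / ``cerebroside``.
    ``hexose`` (``glc``/``gal``) is None for the blank; ``saturation`` (the
    number of C=C bonds in the ceramide, 0 or 1) and ``chain_length`` are
    None unless the analyte is a cerebroside.
    """

    category: str
    hexose: str | None = None
    saturation: int | None = None
    chain_length: int | None = None

    def __post_init__(self):
        if self.category not in _CATEGORIES:
            raise ValidationError(f"unknown category {self.category!r}")
        if self.category == "blank":
            if self.hexose is not None or self.saturation is not None \
                    or self.chain_length is not None:
                raise ValidationError("blank label carries no structure fields")
            return
        if self.hexose not in _HEXOSES:
            raise ValidationError(f"unknown hexose {self.hexose!r}")
        if self.category == "monosaccharide":
            if self.saturation is not None or self.chain_length is not None:
                raise ValidationError(
                    "monosaccharide label carries no ceramide fields"
                )
            return
        # cerebroside
        if self.saturation not in (0, 1):
            raise ValidationError("cerebroside saturation must be 0 or 1")
        if self.chain_length not in CHAIN_LENGTHS:
            raise ValidationError(
                f"chain length must be one of {CHAIN_LENGTHS}, "
                f"got {self.chain_length!r}"
            )

    # -- constructors -----------------------------------------------------
    @classmethod
    def blank(cls) -> "AnalyteLabel":
        return cls("blank")

    @classmethod
    def monosaccharide(cls, hexose: str) -> "AnalyteLabel":
        return cls("monosaccharide", hexose=hexose)

    @classmethod
    def cerebroside(cls, hexose: str, chain_length: int,
                    saturation: int = 0) -> "AnalyteLabel":
        return cls("cerebroside", hexose=hexose, saturation=saturation,
                   chain_length=chain_length)

    @classmethod
    def from_nomenclature(cls, name: str) -> "AnalyteLabel":
        """Parse a conventional name (inverse of :meth:`nomenclature`)."""
        name = name.strip()
        if name in ("MPBA", "MPBA blank", "blank"):
            return cls.blank()
        if name == "glucose":
            return cls.monosaccharide("glc")
        if name == "galactose":
            return cls.monosaccharide("gal")
        for prefix, hexose in (("GlcCer", "glc"), ("GalCer", "gal")):
            if name.startswith(prefix):
                body = name[len(prefix):]
                if ":" in body:
                    chain_s, sat_s = body.split(":", 1)
                else:
                    chain_s, sat_s = body, "0"
                try:
                    chain, sat = int(chain_s), int(sat_s)
                except ValueError:
                    raise ValidationError(f"cannot parse label {name!r}")
                return cls.cerebroside(hexose, chain, sat)
        raise ValidationError(f"cannot parse label {name!r}")

    # -- rendering --------------------------------------------------------
    def nomenclature(self) -> str:
        """Conventional name; a pure function of the fields."""
        if self.category == "blank":
            return "MPBA blank"
        if self.category == "monosaccharide":
            return "glucose" if self.hexose == "glc" else "galactose"
        stem = ("GlcCer" if self.hexose == "glc" else "GalCer")
        name = f"{stem}{self.chain_length}"
        if self.saturation:
            name += f":{self.saturation}"
        return name

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.nomenclature()


def all_labels() -> list[AnalyteLabel]:
    """The 14 in-scope analyte classes in canonical order."""
    return [AnalyteLabel.from_nomenclature(n) for n in CLASS_ORDER]


def _format_concentration(c: float) -> str:
    """Canonical decimal string for a molar concentration."""
    if c == 0:
        return "0"
    return f"{c:g}"


@dataclass
class SpectrumSet:
    """Parallel collections of spectra, labels and concentrations.

    ``spectra`` entries may be None for a manifest skeleton (labels and file
    references read, spectra not yet loaded).  ``concentration_strings`` keeps
    the manifest's decimal strings so round trips are byte-exact.
    """

    spectra: list
    labels: list
    concentrations: np.ndarray
    replicates: list
    files: list | None = None
    concentration_strings: list | None = None

    def __post_init__(self):
        n = len(self.labels)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if len(self.spectra) != n or self.concentrations.size != n \
                or len(self.replicates) != n:
            raise ValidationError("spectra/labels/concentrations/replicates "
                                  "must have equal length")
        if self.files is not None and len(self.files) != n:
            raise ValidationError("files must parallel the other collections")
        if self.concentration_strings is None:
            self.concentration_strings = [
                _format_concentration(c) for c in self.concentrations
            ]
        elif len(self.concentration_strings) != n:
            raise ValidationError("concentration_strings length mismatch")

    def __len__(self) -> int:
        return len(self.labels)

    def replicate_counts(self) -> dict:
        """Counts per (nomenclature, concentration string) cell."""
        counts: dict = {}
        for lab, cs in zip(self.labels, self.concentration_strings):
            key = (lab.nomenclature(), cs)
            counts[key] = counts.get(key, 0) + 1
        return counts

    def subset(self, mask) -> "SpectrumSet":
        idx = np.flatnonzero(np.asarray(mask))
        return SpectrumSet(
            [self.spectra[i] for i in idx],
            [self.labels[i] for i in idx],
            self.concentrations[idx],
            [self.replicates[i] for i in idx],
            None if self.files is None else [self.files[i] for i in idx],
            [self.concentration_strings[i] for i in idx],
        )

    def label_frame(self) -> pd.DataFrame:
        """Labels and metadata as a DataFrame (one row per spectrum)."""
        return pd.DataFrame(
            {
                "analyte": [l.nomenclature() for l in self.labels],
                "category": [l.category for l in self.labels],
                "hexose": [l.hexose for l in self.labels],
                "saturation": [l.saturation for l in self.labels],
                "chain_length": [l.chain_length for l in self.labels],
                "concentration_M": self.concentrations,
                "replicate": list(self.replicates),
            }
        )


# ---------------------------------------------------------------------------
# spectrum files
# ---------------------------------------------------------------------------

def read_spectrum(path, delimiter: str | None = None,
                  comment: str = "#") -> Spectrum:
    """Read a two-column delimited spectrum file.

    Header lines starting with ``comment`` are parsed as ``key: value``
    metadata when they contain a colon.  Rows are sorted by ascending
    wavenumber; duplicate wavenumbers are rejected.

    Raises
    ------
    SpectrumParseError
        On a malformed row (with its 1-based line number).
    EmptySpectrumError
        If fewer than two data points are present.
    """
    path = Path(path)
    meta: dict = {}
    wn: list[float] = []
    it: list[float] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(comment):
                body = line[len(comment):].strip()
                if ":" in body:
                    key, _, value = body.partition(":")
                    meta[key.strip()] = value.strip()
                continue
            if delimiter is None:
                parts = line.replace(",", " ").replace("\t", " ").split()
            else:
                parts = [p.strip() for p in line.split(delimiter)]
            if len(parts) < 2:
                raise SpectrumParseError("expected two columns", line=lineno)
            try:
                wn.append(float(parts[0]))
                it.append(float(parts[1]))
            except ValueError:
                raise SpectrumParseError(
                    f"non-numeric cell in {parts[:2]!r}", line=lineno
                )
    if len(wn) < 2:
        raise EmptySpectrumError(f"{path}: fewer than two data points")
    order = np.argsort(wn, kind="stable")
    wn_a = np.asarray(wn, float)[order]
    it_a = np.asarray(it, float)[order]
    if np.any(np.diff(wn_a) == 0):
        raise SpectrumParseError(f"{path}: duplicate wavenumbers")
    return Spectrum(wn_a, it_a, meta)


def write_spectrum(sp: Spectrum, path, delimiter: str = ",") -> None:
    """Write a spectrum as two-column delimited text with a ``#`` header."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        for key in sorted(sp.meta):
            fh.write(f"# {key}: {sp.meta[key]}\n")
        for x, y in zip(sp.wavenumbers, sp.intensities):
            fh.write(f"{x:.6f}{delimiter}{y:.8g}\n")


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------

_MANIFEST_COLUMNS = (
    "file", "category", "hexose", "saturation", "chain_length",
    "concentration_M", "replicate",
)


def write_manifest(sset: SpectrumSet, path) -> None:
    """Write the label manifest CSV for a spectrum set.

    The manifest holds file references, the structured label fields, the
    concentration as a decimal string and the replicate id.  Writing, reading
    and writing again yields byte-identical files.
    """
    path = Path(path)
    files = sset.files or [""] * len(sset)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(_MANIFEST_COLUMNS)
        for i, lab in enumerate(sset.labels):
            writer.writerow([
                files[i],
                lab.category,
                lab.hexose or "",
                "" if lab.saturation is None else lab.saturation,
                "" if lab.chain_length is None else lab.chain_length,
                sset.concentration_strings[i],
                sset.replicates[i],
            ])


def read_manifest(path) -> SpectrumSet:
    """Read a manifest CSV into a :class:`SpectrumSet` skeleton.

    Spectra are not loaded (entries are None); ``files`` holds the references.
    """
    path = Path(path)
    labels, concs, conc_strings, reps, files = [], [], [], [], []
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or tuple(header) != _MANIFEST_COLUMNS:
            raise ValidationError(
                f"{path}: manifest header must be {','.join(_MANIFEST_COLUMNS)}"
            )
        for row in reader:
            if not row:
                continue
            fname, category, hexose, sat, chain, conc, rep = row
            labels.append(AnalyteLabel(
                category=category,
                hexose=hexose or None,
                saturation=int(sat) if sat != "" else None,
                chain_length=int(chain) if chain != "" else None,
            ))
            try:
                concs.append(float(conc))
            except ValueError:
                raise ValidationError(
                    f"{path}: bad concentration string {conc!r}"
                )
            conc_strings.append(conc)
            reps.append(int(rep))
            files.append(fname)
    return SpectrumSet(
        spectra=[None] * len(labels),
        labels=labels,
        concentrations=np.asarray(concs, float),
        replicates=reps,
        files=files,
        concentration_strings=conc_strings,
    )
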