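"""Reading quantified-peptide tables and protein databases.

Two table dialects are supported:

* **wide** — a MetaMorpheus-style ``AllQuantifiedPeptides.psmtsv`` layout:
  one row per peptidoform with columns ``Sequence``, ``Base Sequence``,
  ``Protein Groups`` and, for each MS file ``<f>``, a light column
  ``Intensity_<f>`` paired with a heavy column ``Heavy Intensity_<f>``.
* **long** — one row per (peptidoform, MS file) with columns
  ``sequence, full_sequence, protein_id, file, light, heavy`` and optional
  three-way label intensities ``intensity_00, intensity_08, intensity_88``
  for missed-cleavage peptides.

Chase timepoints are parsed from MS file names containing ``_dX_`` or
``_Xd_`` tokens (X in days).  A zero intensity is treated as missing by
default (standard label-free quantification convention), and a ratio
``light / (light + heavy)`` is only defined when both intensities are
present.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PeptideObservation",
    "PeptideSeries",
    "parse_timepoint",
    "read_quantified_peptides",
    "write_long_table",
    "filter_series",
    "remap_proteins",
    "read_fasta",
    "read_uniprot_xml",
    "read_protein_database",
    "MissingTimepointError",
    "AmbiguousTimepointError",
    "TableFormatError",
]


class MissingTimepointError(ValueError):
    """No ``_dX_`` / ``_Xd_`` token found in an MS file name."""


class AmbiguousTimepointError(ValueError):
    """Conflicting timepoint tokens found in one MS file name."""


class TableFormatError(ValueError):
    """Unparseable quantified-peptide table."""


@dataclass(frozen=True)
class PeptideObservation:
    """One (MS file, timepoint) measurement of a peptidoform."""

    source_file: str
    timepoint: float
    light: float | None
    heavy: float | None
    # Optional three-way label intensities of a missed-cleavage peptide.
    intensity_00: float | None = None
    intensity_08: float | None = None
    intensity_88: float | None = None

    @property
    def ratio(self) -> float | None:
        """Lys0/(Lys0+Lys8), defined only when both intensities are present."""
        if self.light is None or self.heavy is None:
            return None
        total = self.light + self.heavy
        if total <= 0:
            return None
        return self.light / total


@dataclass
class PeptideSeries:
    """All observations of one peptidoform in one tissue."""

    base_sequence: str
    full_sequence: str
    protein_id: str
    observations: list[PeptideObservation] = field(default_factory=list)

    @property
    def n_valid(self) -> int:
        return sum(1 for o in self.observations if o.ratio is not None)

    @property
    def total_intensity(self) -> float:
        tot = 0.0
        for o in self.observations:
            if o.light is not None:
                tot += o.light
            if o.heavy is not None:
                tot += o.heavy
        return tot

    @property
    def missed_cleavage(self) -> bool:
        """Two lysines (one missed Lys-C cleavage)."""
        return self.base_sequence.count("K") >= 2

    def valid_points(self) -> tuple[np.ndarray, np.ndarray]:
        """(timepoints, ratios) of the valid observations, in input order."""
        t, r = [], []
        for o in self.observations:
            ratio = o.ratio
            if ratio is not None:
                t.append(o.timepoint)
                r.append(ratio)
        return np.asarray(t, dtype=float), np.asarray(r, dtype=float)

    def counts_per_timepoint(self) -> dict[float, int]:
        out: dict[float, int] = {}
        for o in self.observations:
            if o.ratio is not None:
                out[o.timepoint] = out.get(o.timepoint, 0) + 1
        return out


_TOKEN_DX = re.compile(r"_d(\d+)(?=_)")
_TOKEN_XD = re.compile(r"_(\d+)d(?=_|\.|$)")


def parse_timepoint(file_name: str) -> int:
    """Parse the chase timepoint (days) from an MS file name.

    Recognizes ``_dX_`` and ``_Xd_`` tokens where X is a positive integer;
    the right delimiter of ``_Xd`` may be an underscore, an extension dot,
    or the end of the name (``180628_Liver_3d_bio1.raw`` -> 3).
    """
    hits = [int(m) for m in _TOKEN_DX.findall(file_name)]
    hits += [int(m) for m in _TOKEN_XD.findall(file_name)]
    hits = [h for h in hits if h > 0]
    if not hits:
        raise MissingTimepointError(
            f"no _dX_ / _Xd_ timepoint token in file name {file_name!r}"
        )
    if len(set(hits)) > 1:
        raise AmbiguousTimepointError(
            f"conflicting timepoint tokens {sorted(set(hits))} in {file_name!r}"
        )
    return hits[0]


def _clean_intensity(value, zero_is_missing: bool) -> float | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    try:
        v = float(value)
    except (TypeError, ValueError):
        return None
    if np.isnan(v):
        return None
    if v == 0.0 and zero_is_missing:
        return None
    if v < 0:
        return None
    return v


def _detect_dialect(columns: Sequence[str]) -> str:
    lower = {c.lower() for c in columns}
    if {"file", "light", "heavy"} <= lower:
        return "long"
    if any(c.startswith("Intensity_") for c in columns):
        return "wide"
    raise TableFormatError(
        "could not detect table dialect: need either long-format columns "
        "(sequence, file, light, heavy) or wide-format Intensity_<file> columns; "
        f"got {list(columns)!r}"
    )


def read_quantified_peptides(
    path: str | Path,
    dialect: str = "auto",
    zero_is_missing: bool = True,
) -> list[PeptideSeries]:
    """Read a quantified-peptide table into one PeptideSeries per peptidoform.

    Observations whose light or heavy intensity is missing have no defined
    ratio; they are retained on the series (for accounting) but never
    contribute to fitting.  Series are returned sorted by full sequence so
    downstream results do not depend on file row order.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.columns.size < 2:
        raise TableFormatError(f"{path}: not a tab-separated table with a header")
    if dialect == "auto":
        dialect = _detect_dialect(df.columns)
    if dialect == "long":
        series = _read_long(df, zero_is_missing)
    elif dialect == "wide":
        series = _read_wide(df, zero_is_missing)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if not series:
        raise TableFormatError(f"{path}: no peptide series could be read")
    return sorted(series, key=lambda s: s.full_sequence)


def _col(df: pd.DataFrame, *names: str) -> str | None:
    lower = {c.lower(): c for c in df.columns}
    for n in names:
        if n.lower() in lower:
            return lower[n.lower()]
    return None


def _read_long(df: pd.DataFrame, zero_is_missing: bool) -> list[PeptideSeries]:
    c_seq = _col(df, "sequence", "base sequence")
    c_full = _col(df, "full_sequence", "full sequence")
    c_prot = _col(df, "protein_id", "protein", "protein groups")
    c_file = _col(df, "file")
    c_light = _col(df, "light")
    c_heavy = _col(df, "heavy")
    if c_seq is None or c_file is None or c_light is None or c_heavy is None:
        raise TableFormatError(
            "long dialect needs columns: sequence, file, light, heavy"
        )
    c00 = _col(df, "intensity_00")
    c08 = _col(df, "intensity_08")
    c88 = _col(df, "intensity_88")
    out: dict[str, PeptideSeries] = {}
    for _, row in df.iterrows():
        base = str(row[c_seq]).strip()
        full = str(row[c_full]).strip() if c_full else base
        prot = str(row[c_prot]).strip() if c_prot else "UNKNOWN"
        fname = str(row[c_file]).strip()
        tp = float(parse_timepoint(fname))
        obs = PeptideObservation(
            source_file=fname,
            timepoint=tp,
            light=_clean_intensity(row[c_light], zero_is_missing),
            heavy=_clean_intensity(row[c_heavy], zero_is_missing),
            intensity_00=_clean_intensity(row[c00], True) if c00 else None,
            intensity_08=_clean_intensity(row[c08], True) if c08 else None,
            intensity_88=_clean_intensity(row[c88], True) if c88 else None,
        )
        s = out.get(full)
        if s is None:
            s = PeptideSeries(base, full, prot)
            out[full] = s
        s.observations.append(obs)
    return list(out.values())


_WIDE_LIGHT = re.compile(r"^Intensity_(.+)$")
_WIDE_HEAVY = re.compile(r"^Heavy Intensity_(.+)$")


def _read_wide(df: pd.DataFrame, zero_is_missing: bool) -> list[PeptideSeries]:
    c_full = _col(df, "Sequence", "full sequence")
    c_base = _col(df, "Base Sequence")
    c_prot = _col(df, "Protein Groups", "protein")
    if c_full is None:
        raise TableFormatError("wide dialect needs a 'Sequence' column")
    light_cols = {m.group(1): c for c in df.columns if (m := _WIDE_LIGHT.match(c))}
    heavy_cols = {m.group(1): c for c in df.columns if (m := _WIDE_HEAVY.match(c))}
    files = sorted(set(light_cols) & set(heavy_cols))
    if not files:
        raise TableFormatError(
            "wide dialect needs paired 'Intensity_<file>' / 'Heavy Intensity_<file>' columns"
        )
    out: list[PeptideSeries] = []
    for _, row in df.iterrows():
        full = str(row[c_full]).strip()
        base = str(row[c_base]).strip() if c_base else _strip_modifications(full)
        prot = str(row[c_prot]).strip() if c_prot else "UNKNOWN"
        s = PeptideSeries(base, full, prot)
        for f in files:
            tp = float(parse_timepoint(f))
            s.observations.append(
                PeptideObservation(
                    source_file=f,
                    timepoint=tp,
                    light=_clean_intensity(row[light_cols[f]], zero_is_missing),
                    heavy=_clean_intensity(row[heavy_cols[f]], zero_is_missing),
                )
            )
        out.append(s)
    return out


_MOD_TOKEN = re.compile(r"\[[^\]]*\]")


def _strip_modifications(full_sequence: str) -> str:
    """Base amino-acid sequence of a peptidoform (bracketed mods removed)."""
    return _MOD_TOKEN.sub("", full_sequence)


def modification_tokens(full_sequence: str) -> list[str]:
    """Bracketed modification annotations of a peptidoform, in order."""
    return [m.group(0)[1:-1] for m in _MOD_TOKEN.finditer(full_sequence)]


def write_long_table(series: Iterable[PeptideSeries], path: str | Path) -> None:
    """Write the normalized long-format TSV (one row per observation)."""
    rows = []
    for s in series:
        for o in s.observations:
            rows.append(
                {
                    "sequence": s.base_sequence,
                    "full_sequence": s.full_sequence,
                    "protein_id": s.protein_id,
                    "file": o.source_file,
                    "timepoint_d": o.timepoint,
                    "light": "" if o.light is None else repr(o.light),
                    "heavy": "" if o.heavy is None else repr(o.heavy),
                    "ratio": "" if o.ratio is None else f"{o.ratio:.10g}",
                    "intensity_00": "" if o.intensity_00 is None else repr(o.intensity_00),
                    "intensity_08": "" if o.intensity_08 is None else repr(o.intensity_08),
                    "intensity_88": "" if o.intensity_88 is None else repr(o.intensity_88),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def filter_series(
    series: Sequence[PeptideSeries],
    min_total: int = 6,
    min_single_timepoint: int = 3,
) -> tuple[list[PeptideSeries], list[tuple[PeptideSeries, str]]]:
    """Apply the validity filter: at least ``min_total`` valid ratios of which
    at least ``min_single_timepoint`` come from a single timepoint.

    Returns (kept, discarded-with-reasons).  Idempotent and order-preserving.
    """
    kept: list[PeptideSeries] = []
    discarded: list[tuple[PeptideSeries, str]] = []
    for s in series:
        if s.n_valid < min_total:
            discarded.append((s, "too-few-total"))
            continue
        per_tp = s.counts_per_timepoint()
        if not per_tp or max(per_tp.values()) < min_single_timepoint:
            discarded.append((s, "no-anchor-timepoint"))
            continue
        kept.append(s)
    return kept, discarded


def remap_proteins(
    series: Sequence[PeptideSeries],
    database: Mapping[str, str],
    strict_cleavage: bool = False,
) -> tuple[list[PeptideSeries], dict[str, int]]:
    """Undo protein parsimony by exact substring search of each base sequence.

    A peptide matching two or more database proteins gets the accessions
    sorted alphabetically and joined with ``|`` (e.g. ``A|B``); such shared
    peptides never contribute to any individual constituent protein.
    Peptides matching nothing keep their original identifier and are counted.

    With ``strict_cleavage`` the residue preceding a match must be K (or the
    protein start), consistent with Lys-C digestion.

    Returns (remapped series, stats) where stats counts unique/shared/
    unmatched peptides.  Observations are never modified.
    """
    if not database:
        raise ValueError("protein database is empty")
    accs = sorted(database)
    stats = {"unique": 0, "shared": 0, "unmatched": 0}
    cache: dict[str, list[str]] = {}
    out: list[PeptideSeries] = []
    for s in series:
        base = s.base_sequence
        matches = cache.get(base)
        if matches is None:
            matches = []
            for acc in accs:
                seq = database[acc]
                start = seq.find(base)
                while start != -1:
                    if not strict_cleavage or start == 0 or seq[start - 1] == "K":
                        matches.append(acc)
                        break
                    start = seq.find(base, start + 1)
            cache[base] = matches
        if not matches:
            stats["unmatched"] += 1
            new_id = s.protein_id
        elif len(matches) == 1:
            stats["unique"] += 1
            new_id = matches[0]
        else:
            stats["shared"] += 1
            new_id = "|".join(matches)
        out.append(
            PeptideSeries(
                base_sequence=s.base_sequence,
                full_sequence=s.full_sequence,
                protein_id=new_id,
                observations=list(s.observations),
            )
        )
    return out, stats


_UNIPROT_HEADER = re.compile(r"^(?:sp|tr)\|([^|]+)\|")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA protein database into {accession: uppercase sequence}.

    The accession is the UniProt middle field of ``sp|ACC|NAME`` headers,
    otherwise the first whitespace-delimited token.
    """
    from pyteomics import fasta

    out: dict[str, str] = {}
    for header, seq in fasta.read(str(path)):
        m = _UNIPROT_HEADER.match(header)
        acc = m.group(1) if m else header.split()[0]
        out[acc] = seq.upper()
    return out


def read_uniprot_xml(path: str | Path) -> dict[str, str]:
    """Read a UniProt XML database into {primary accession: sequence}."""
    from Bio import SeqIO

    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "uniprot-xml"):
        out[rec.id] = str(rec.seq).upper()
    return out


def read_protein_database(path: str | Path) -> dict[str, str]:
    """Dispatch on extension: ``.xml`` -> UniProt XML, otherwise FASTA."""
    path = Path(path)
    if path.suffix.lower() == ".xml":
        return read_uniprot_xml(path)
    return read_fasta(path)
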