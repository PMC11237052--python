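"""Reading and writing NanoString nCounter artifacts.

The nCounter platform emits one RCC file per sample/lane: a small sectioned
text file (``<Header>``, ``<Sample_Attributes>``, ``<Lane_Attributes>``,
``<Code_Summary>``) in a CSV dialect.  The ``Code_Summary`` section carries
one row per probe with its code class (Endogenous, Housekeeping, Positive,
Negative), accession and digital count.  This module parses and writes that
format, holds the panel definition (probe -> code class, with the spiked-in
positive-control concentration ladder), and assembles per-sample counts into
a cohort-level matrix that the QC/normalization stages consume.

Signature weight files (e.g. the 18-gene tumor inflammation signature) and
GMT gene-set collections are read here as well.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

CODE_CLASSES = ("Endogenous", "Housekeeping", "Positive", "Negative")

#: Spiked-in positive-control ladder concentrations (fM), standard nCounter
#: four-fold geometric series, highest first.
POSITIVE_LADDER_FM = (128.0, 32.0, 8.0, 2.0, 0.5, 0.125)


class RCCParseError(ValueError):
    """Raised when an RCC file is malformed."""


class PanelConsistencyError(ValueError):
    """Raised when samples and panel definitions disagree."""


@dataclass(frozen=True)
class PanelDefinition:
    """Probe -> code-class map with positive-control concentrations.

    ``table`` has columns ``probe``, ``code_class``, ``accession``,
    ``expected_conc_fM`` (0 for non-Positive probes), one row per probe,
    in panel order.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = {"probe", "code_class", "accession", "expected_conc_fM"}
        if not required.issubset(t.columns):
            raise ValueError(f"panel table missing columns: {sorted(required - set(t.columns))}")
        if t["probe"].duplicated().any():
            dupes = t.loc[t["probe"].duplicated(), "probe"].tolist()
            raise ValueError(f"duplicate probe names in panel: {dupes}")
        bad = set(t["code_class"]) - set(CODE_CLASSES)
        if bad:
            raise ValueError(f"unknown code classes: {sorted(bad)}")
        if not (t["code_class"] == "Housekeeping").any():
            raise ValueError("panel must contain at least one Housekeeping probe")
        pos = t.loc[t["code_class"] == "Positive", "expected_conc_fM"].to_numpy(float)
        if len(pos):
            ranked = np.sort(pos)[::-1]
            if len(np.unique(pos)) != len(pos) or np.any(np.diff(ranked) >= 0):
                raise ValueError("Positive probes must have strictly decreasing distinct concentrations")

    @property
    def probes(self) -> list[str]:
        return self.table["probe"].tolist()

    def probes_of_class(self, code_class: str) -> list[str]:
        return self.table.loc[self.table["code_class"] == code_class, "probe"].tolist()

    @property
    def housekeeping_probes(self) -> list[str]:
        return self.probes_of_class("Housekeeping")

    @property
    def endogenous_probes(self) -> list[str]:
        return self.probes_of_class("Endogenous")

    @property
    def positive_probes(self) -> list[str]:
        """Positive probes sorted by ladder rank (highest concentration first)."""
        pos = self.table[self.table["code_class"] == "Positive"]
        return pos.sort_values("expected_conc_fM", ascending=False)["probe"].tolist()

    def code_class_of(self, probe: str) -> str:
        row = self.table[self.table["probe"] == probe]
        if row.empty:
            raise KeyError(probe)
        return row["code_class"].iloc[0]


@dataclass
class RawSample:
    """Counts and attributes parsed from one RCC file."""

    sample_id: str
    counts: dict[str, int]
    sample_attributes: dict[str, str] = field(default_factory=dict)
    lane_attributes: dict[str, str] = field(default_factory=dict)


@dataclass
class CountsMatrix:
    """Samples x probes count matrix with normalization provenance.

    ``stage`` advances raw -> posctrl_normalized -> fully_normalized; the
    per-sample scale factors applied at each stage are retained so that any
    normalized value is traceable back to its raw count.
    """

    data: pd.DataFrame  # index = samples, columns = probes
    stage: str = "raw"
    posctrl_factor: pd.Series | None = None
    hk_factor: pd.Series | None = None

    STAGES = ("raw", "posctrl_normalized", "fully_normalized")

    def __post_init__(self) -> None:
        if self.stage not in self.STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.data.isna().any().any():
            raise ValueError("counts matrix contains NaN")
        for fac in (self.posctrl_factor, self.hk_factor):
            if fac is not None and (fac <= 0).any():
                raise ValueError("normalization factors must be positive")

    @property
    def samples(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def probes(self) -> list[str]:
        return self.data.columns.tolist()


@dataclass
class SignatureDefinition:
    """Named (gene, weight) vector applied to transformed expression."""

    name: str
    entries: pd.Series  # index = gene, values = weight
    transform: str = "log2_of_counts"  # or "zscored_log_expression"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.entries) == 0:
            raise ValueError("signature must have at least one entry")
        if self.entries.index.duplicated().any():
            raise ValueError("duplicate genes in signature")
        if not np.all(np.isfinite(self.entries.to_numpy(float))):
            raise ValueError("signature weights must be finite")

    @property
    def genes(self) -> list[str]:
        return self.entries.index.tolist()


# GeneSetCollection: plain mapping set_name -> list of gene symbols.
GeneSetCollection = dict


# ---------------------------------------------------------------------------
# RCC reading / writing
# ---------------------------------------------------------------------------

def _split_sections(text: str, path: str) -> dict[str, list[str]]:
    """Split RCC text into sections keyed by lower-case tag name."""
    sections: dict[str, list[str]] = {}
    current: str | None = None
    for line in text.splitlines():
        stripped = line.strip()
        if stripped.startswith("<") and stripped.endswith(">"):
            tag = stripped[1:-1]
            if tag.startswith("/"):
                current = None
            else:
                current = tag.lower()
                sections.setdefault(current, [])
            continue
        if current is not None and stripped:
            sections[current].append(line)
    if not sections:
        raise RCCParseError(f"{path}: no RCC sections found")
    return sections


def _parse_csv_rows(lines: list[str]) -> list[list[str]]:
    reader = csv.reader(io.StringIO("\n".join(lines)))
    return [row for row in reader if row and any(f.strip() for f in row)]


def _parse_attributes(lines: list[str]) -> dict[str, str]:
    out: dict[str, str] = {}
    for row in _parse_csv_rows(lines):
        key = row[0].strip()
        out[key] = row[1].strip() if len(row) > 1 else ""
    return out


def read_rcc(path: str | Path) -> RawSample:
    """Parse one RCC file into a :class:`RawSample`.

    Section tags are matched case-insensitively and both quoted and unquoted
    CSV fields are accepted, since files from different instrument software
    versions vary in both.
    """
    path = Path(path)
    sections = _split_sections(path.read_text(), str(path))
    if "code_summary" not in sections:
        raise RCCParseError(f"{path}: missing Code_Summary section")
    if "lane_attributes" not in sections:
        raise RCCParseError(f"{path}: missing Lane_Attributes section")

    sample_attrs = _parse_attributes(sections.get("sample_attributes", []))
    lane_attrs = _parse_attributes(sections["lane_attributes"])

    rows = _parse_csv_rows(sections["code_summary"])
    if rows and rows[0][0].strip().lower() == "codeclass":
        rows = rows[1:]
    counts: dict[str, int] = {}
    for row in rows:
        if len(row) < 4:
            raise RCCParseError(f"{path}: malformed Code_Summary row: {row}")
        _, name, _, count_str = (f.strip() for f in row[:4])
        try:
            count = int(count_str)
        except ValueError as exc:
            raise RCCParseError(f"{path}: non-integer count in Code_Summary row for probe {name!r}: {count_str!r}") from exc
        if count < 0:
            raise RCCParseError(f"{path}: negative count for probe {name!r}")
        if name in counts:
            raise RCCParseError(f"{path}: probe {name!r} appears more than once")
        counts[name] = count

    sample_id = sample_attrs.get("ID") or path.stem
    return RawSample(sample_id=sample_id, counts=counts,
                     sample_attributes=sample_attrs, lane_attributes=lane_attrs)


def write_rcc(sample: RawSample, panel: PanelDefinition, path: str | Path) -> Path:
    """Write ``sample`` to an RCC file readable by :func:`read_rcc`."""
    if not sample.counts:
        raise PanelConsistencyError("sample has an empty counts map")
    extra = set(sample.counts) - set(panel.probes)
    if extra:
        raise PanelConsistencyError(f"sample probes absent from panel: {sorted(extra)}")
    missing = set(panel.probes) - set(sample.counts)
    if missing:
        raise PanelConsistencyError(f"sample missing panel probes: {sorted(missing)}")

    path = Path(path)
    lines: list[str] = []
    lines += ["<Header>", "FileVersion,1.7", "SoftwareVersion,immunoprofiler", "</Header>"]
    lines.append("<Sample_Attributes>")
    attrs = dict(sample.sample_attributes)
    attrs.setdefault("ID", sample.sample_id)
    attrs["ID"] = sample.sample_id
    for key, value in attrs.items():
        lines.append(f"{key},{value}")
    lines.append("</Sample_Attributes>")
    lines.append("<Lane_Attributes>")
    lane = dict(sample.lane_attributes) or {"ID": "1"}
    for key, value in lane.items():
        lines.append(f"{key},{value}")
    lines.append("</Lane_Attributes>")
    lines.append("<Code_Summary>")
    lines.append("CodeClass,Name,Accession,Count")
    for _, row in panel.table.iterrows():
        probe = row["probe"]
        lines.append(f"{row['code_class']},{probe},{row['accession']},{sample.counts[probe]}")
    lines.append("</Code_Summary>")
    path.write_text("\n".join(lines) + "\n")
    return path


def assemble_counts(samples: Sequence[RawSample], panel: PanelDefinition) -> CountsMatrix:
    """Stack per-sample counts into a raw :class:`CountsMatrix`.

    Row order follows the input sample order; column order follows the panel.
    """
    ids = [s.sample_id for s in samples]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise ValueError(f"duplicate sample ids: {sorted(dupes)}")
    panel_probes = set(panel.probes)
    for s in samples:
        mismatch = panel_probes.symmetric_difference(s.counts)
        if mismatch:
            raise PanelConsistencyError(
                f"sample {s.sample_id!r} probe set differs from panel: {sorted(mismatch)}")
    data = pd.DataFrame(
        [[s.counts[p] for p in panel.probes] for s in samples],
        index=ids, columns=panel.probes, dtype=float)
    return CountsMatrix(data=data, stage="raw")


# ---------------------------------------------------------------------------
# Panel / signature / gene-set files
# ---------------------------------------------------------------------------

def read_panel(path: str | Path) -> PanelDefinition:
    """Read a panel definition CSV (probe,code_class,accession,expected_conc_fM)."""
    table = pd.read_csv(path)
    table.columns = [c.strip() for c in table.columns]
    return PanelDefinition(table=table)


def write_panel(panel: PanelDefinition, path: str | Path) -> Path:
    path = Path(path)
    panel.table.to_csv(path, index=False)
    return path


def read_signature(path: str | Path, name: str | None = None,
                   transform: str = "log2_of_counts") -> SignatureDefinition:
    """Read a two-column (gene, weight) CSV; a header row is optional."""
    path = Path(path)
    rows = _parse_csv_rows(path.read_text().splitlines())
    if not rows:
        raise ValueError(f"{path}: empty signature file")
    # header if second field of first row is non-numeric
    try:
        float(rows[0][1])
    except (ValueError, IndexError):
        rows = rows[1:]
    genes, weights = [], []
    for row in rows:
        if len(row) < 2:
            raise ValueError(f"{path}: malformed signature row: {row}")
        gene = row[0].strip()
        try:
            weight = float(row[1])
        except ValueError as exc:
            raise ValueError(f"{path}: non-numeric weight for gene {gene!r}: {row[1]!r}") from exc
        if gene in genes:
            raise ValueError(f"{path}: duplicate gene {gene!r}")
        genes.append(gene)
        weights.append(weight)
    entries = pd.Series(weights, index=genes, dtype=float)
    return SignatureDefinition(name=name or path.stem, entries=entries, transform=transform)


def tis_signature(path: str | Path | None = None, unit_weights: bool = False) -> SignatureDefinition:
    """The 18-gene tumor inflammation signature.

    By default loads the packaged weight file (weights transcribed from the
    public patent filing covering the signature; the defining publication did
    not print them).  ``path`` substitutes an alternative weighting;
    ``unit_weights=True`` replaces all weights with 1.0, which is flagged in
    the signature metadata so downstream outputs can surface it.
    """
    if path is None:
        with resources.as_file(resources.files("immunoprofiler.data") / "tis_weights.csv") as p:
            sig = read_signature(p, name="TIS")
    else:
        sig = read_signature(path, name="TIS")
    if unit_weights:
        sig = SignatureDefinition(
            name="TIS", entries=pd.Series(1.0, index=sig.entries.index),
            transform=sig.transform, metadata={"unit_weight_fallback": True})
    return sig


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT gene-set file (name, description, genes...)."""
    sets: GeneSetCollection = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line!r}")
        name, genes = fields[0], [g for g in fields[2:] if g]
        if not genes:
            raise ValueError(f"gene set {name!r} is empty")
        if len(set(genes)) != len(genes):
            raise ValueError(f"gene set {name!r} has duplicate genes")
        sets[name] = genes
    return sets


def write_gmt(sets: GeneSetCollection, path: str | Path) -> Path:
    path = Path(path)
    lines = [f"{name}\tna\t" + "\t".join(genes) for name, genes in sets.items()]
    path.write_text("\n".join(lines) + "\n")
    return path
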