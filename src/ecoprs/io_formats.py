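"""Readers, writers and harmonization for the pipeline's file formats.

Three inputs are read from plain text:

* a PGS-Catalog-style scoring file (tab-separated, ``#`` metadata header)
  giving variants, effect alleles and per-copy weights;
* a population x variant effect-allele frequency table (TSV);
* a population prevalence table with 95% confidence bounds (TSV).

``harmonize`` reconciles a scoring model with a frequency table: variants
without an rsID or absent from the table are dropped, and frequencies
reported for the complementary strand or for the opposite allele are
corrected before any scoring happens.
"""

from __future__ import annotations

import json
import math
import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

_RSID_RE = re.compile(r"^rs\d+$")
_CHRPOS_RE = re.compile(r"^(chr)?[0-9XYM]+:\d+$", re.IGNORECASE)
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: harmonization actions, in report order
ACTIONS = (
    "matched",
    "strand_flipped",
    "allele_swapped",
    "excluded_no_rsid",
    "excluded_missing",
    "excluded_palindromic",
)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantWeight:
    """One scored variant: identity, effect allele and per-copy weight."""

    rsid: str | None
    effect_allele: str
    weight: float
    chrom: str | None = None
    pos: int | None = None
    other_allele: str | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.weight):
            raise ValidationError(f"non-finite weight for {self.label}")
        if self.effect_allele not in _COMPLEMENT:
            raise ValidationError(
                f"effect allele {self.effect_allele!r} of {self.label} is not a "
                "single nucleotide A/C/G/T"
            )
        if self.rsid is not None and not _RSID_RE.match(self.rsid):
            raise ValidationError(f"malformed rsID {self.rsid!r}")

    @property
    def label(self) -> str:
        """rsID when present, otherwise a chrom:pos token."""
        if self.rsid:
            return self.rsid
        if self.chrom is not None and self.pos is not None:
            return f"{self.chrom}:{self.pos}"
        return "<unnamed variant>"

    @property
    def is_palindromic(self) -> bool:
        """True when effect/other alleles are strand-ambiguous (A/T or C/G)."""
        return (
            self.other_allele is not None
            and _COMPLEMENT[self.effect_allele] == self.other_allele
        )


@dataclass(frozen=True)
class ScoringModel:
    """An ordered collection of variant weights from one published score."""

    variants: tuple[VariantWeight, ...]
    score_id: str = ""
    trait: str = ""

    def __post_init__(self) -> None:
        if not self.variants:
            raise ValidationError("scoring model has no variants")
        rsids = [v.rsid for v in self.variants if v.rsid is not None]
        if len(rsids) != len(set(rsids)):
            raise ValidationError("duplicate rsIDs in scoring model")

    @property
    def rsids(self) -> tuple[str | None, ...]:
        return tuple(v.rsid for v in self.variants)

    @property
    def weights(self) -> np.ndarray:
        return np.array([v.weight for v in self.variants], dtype=float)

    def __len__(self) -> int:
        return len(self.variants)


@dataclass(frozen=True)
class FrequencyTable:
    """Effect-allele frequencies per population (rows) and variant (columns).

    ``alleles`` optionally records which allele each column's frequency
    refers to, enabling strand/allele harmonization against a scoring model.
    """

    populations: tuple[str, ...]
    variants: tuple[str, ...]
    freq: np.ndarray  # shape (n_populations, n_variants)
    alleles: Mapping[str, str] = field(default_factory=dict)
    sample_sizes: Mapping[str, int] | None = None

    def __post_init__(self) -> None:
        freq = np.asarray(self.freq, dtype=float)
        object.__setattr__(self, "freq", freq)
        if freq.shape != (len(self.populations), len(self.variants)):
            raise ValidationError(
                f"frequency matrix shape {freq.shape} does not match "
                f"{len(self.populations)} populations x {len(self.variants)} variants"
            )
        if len(set(self.populations)) != len(self.populations):
            raise ValidationError("population codes are not unique")
        if np.isnan(freq).any():
            raise ValidationError("frequency matrix has missing cells")
        bad = np.argwhere((freq < 0) | (freq > 1))
        if bad.size:
            i, j = bad[0]
            raise ValidationError(
                f"frequency {freq[i, j]!r} for {self.variants[j]} in "
                f"{self.populations[i]} is outside [0, 1]"
            )

    def frequency(self, population: str, rsid: str) -> float:
        return float(self.freq[self._pop_index(population), self._var_index(rsid)])

    def population_row(self, population: str) -> np.ndarray:
        return self.freq[self._pop_index(population)]

    def _pop_index(self, population: str) -> int:
        try:
            return self.populations.index(population)
        except ValueError:
            raise KeyError(f"unknown population code {population!r}") from None

    def _var_index(self, rsid: str) -> int:
        try:
            return self.variants.index(rsid)
        except ValueError:
            raise KeyError(f"unknown variant {rsid!r}") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.freq, index=list(self.populations), columns=list(self.variants)
        )


@dataclass(frozen=True)
class PrevalenceRecord:
    """Published prevalence for one population, in cases per 100,000 adults."""

    population: str
    country: str
    prevalence: float
    ci_low: float
    ci_high: float
    source: str

    def __post_init__(self) -> None:
        if not (0 < self.ci_low <= self.prevalence <= self.ci_high):
            raise ValidationError(
                f"prevalence CI for {self.population} violates "
                f"0 < ci_low <= prevalence <= ci_high: "
                f"({self.ci_low}, {self.prevalence}, {self.ci_high})"
            )


@dataclass(frozen=True)
class HarmonizationReport:
    """Per-variant harmonization outcome; counts partition the scoring model."""

    actions: Mapping[str, str]  # variant label -> action

    def __post_init__(self) -> None:
        for label, action in self.actions.items():
            if action not in ACTIONS:
                raise ValidationError(f"unknown action {action!r} for {label}")

    @property
    def counts(self) -> dict[str, int]:
        out = {a: 0 for a in ACTIONS}
        for action in self.actions.values():
            out[action] += 1
        return out

    @property
    def n_surviving(self) -> int:
        c = self.counts
        return c["matched"] + c["strand_flipped"] + c["allele_swapped"]


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_scoring_file(path: str | Path) -> ScoringModel:
    """Parse a PGS-Catalog-style scoring file.

    Tab-separated; lines starting with ``#`` carry ``key=value`` metadata
    (``pgs_id``, ``trait_reported`` are picked up when present). Recognised
    columns are ``rsID``, ``chr_name``, ``chr_position``, ``effect_allele``,
    ``other_allele`` and ``effect_weight``; unknown columns are ignored.
    Rows whose rsID field is empty or a bare chrom:pos token are retained
    with ``rsid=None`` — exclusion is harmonize's job, not the parser's.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    header: list[str] | None = None
    rows: list[tuple[int, list[str]]] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    meta[key.strip()] = value.strip()
                continue
            fields = line.split("\t")
            if header is None:
                header = [h.strip() for h in fields]
                continue
            rows.append((lineno, fields))

    if header is None:
        raise FormatError(f"{path}: no header line found")
    required = {"rsID", "effect_allele", "effect_weight"}
    missing = required - set(header)
    if missing:
        raise FormatError(f"{path}: missing required columns {sorted(missing)}")
    if not rows:
        raise ValidationError(f"{path}: scoring file has no data rows")

    col = {name: i for i, name in enumerate(header)}

    def get(fields: list[str], name: str) -> str:
        i = col.get(name)
        return fields[i].strip() if i is not None and i < len(fields) else ""

    variants: list[VariantWeight] = []
    for lineno, fields in rows:
        raw_rsid = get(fields, "rsID")
        rsid: str | None
        if not raw_rsid or _CHRPOS_RE.match(raw_rsid):
            rsid = None
        elif _RSID_RE.match(raw_rsid):
            rsid = raw_rsid
        else:
            raise FormatError(f"{path}:{lineno}: unrecognisable rsID {raw_rsid!r}")
        raw_weight = get(fields, "effect_weight")
        try:
            weight = float(raw_weight)
        except ValueError:
            raise FormatError(
                f"{path}:{lineno}: unparseable effect_weight {raw_weight!r}"
            ) from None
        chrom = get(fields, "chr_name") or None
        if rsid is None and chrom is None and _CHRPOS_RE.match(raw_rsid or ""):
            chrom = raw_rsid.split(":")[0]
        raw_pos = get(fields, "chr_position")
        pos = int(raw_pos) if raw_pos else None
        if rsid is None and pos is None and raw_rsid and _CHRPOS_RE.match(raw_rsid):
            pos = int(raw_rsid.split(":")[1])
        variants.append(
            VariantWeight(
                rsid=rsid,
                effect_allele=get(fields, "effect_allele"),
                other_allele=get(fields, "other_allele") or None,
                weight=weight,
                chrom=chrom,
                pos=pos,
            )
        )
    return ScoringModel(
        variants=tuple(variants),
        score_id=meta.get("pgs_id", ""),
        trait=meta.get("trait_reported", ""),
    )


def _parse_freq_header(token: str) -> tuple[str, str | None]:
    """Split a frequency-column header into (rsid, annotated allele or None)."""
    if ":" in token:
        rsid, _, allele = token.partition(":")
        allele = allele.strip().upper()
        if allele not in _COMPLEMENT:
            raise FormatError(f"bad allele annotation in column {token!r}")
        return rsid.strip(), allele
    return token.strip(), None


def read_frequency_table(path: str | Path) -> FrequencyTable:
    """Read a TSV of effect-allele frequencies.

    First column is the population code; the header names one variant per
    remaining column, either as a bare rsid or as ``rsid:ALLELE`` when the
    file records which allele the frequency refers to.
    """
    path = Path(path)
    lines = [
        ln.rstrip("\n")
        for ln in path.read_text(encoding="utf-8").splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    if len(lines) < 2:
        raise FormatError(f"{path}: need a header and at least one data row")
    header = lines[0].split("\t")
    variants: list[str] = []
    alleles: dict[str, str] = {}
    for token in header[1:]:
        rsid, allele = _parse_freq_header(token)
        variants.append(rsid)
        if allele is not None:
            alleles[rsid] = allele
    populations: list[str] = []
    freq_rows: list[list[float]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != len(header):
            raise FormatError(
                f"{path}:{lineno}: expected {len(header)} columns, got {len(fields)}"
            )
        populations.append(fields[0].strip())
        row: list[float] = []
        for rsid, cell in zip(variants, fields[1:]):
            try:
                value = float(cell)
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: unparseable frequency {cell!r} for {rsid}"
                ) from None
            if not 0.0 <= value <= 1.0:
                raise ValidationError(
                    f"{path}:{lineno}: frequency {value} for {rsid} in "
                    f"{fields[0].strip()} is outside [0, 1]"
                )
            row.append(value)
        freq_rows.append(row)
    return FrequencyTable(
        populations=tuple(populations),
        variants=tuple(variants),
        freq=np.array(freq_rows, dtype=float),
        alleles=alleles,
    )


def read_prevalence_table(path: str | Path) -> list[PrevalenceRecord]:
    """Read a TSV prevalence table (per 100,000 adults, with 95% CI bounds)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: {exc}") from None
    required = ["population", "country", "prevalence", "ci_low", "ci_high", "source"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    records: list[PrevalenceRecord] = []
    for _, row in df.iterrows():
        try:
            records.append(
                PrevalenceRecord(
                    population=str(row["population"]).strip(),
                    country=str(row["country"]).strip(),
                    prevalence=float(row["prevalence"]),
                    ci_low=float(row["ci_low"]),
                    ci_high=float(row["ci_high"]),
                    source=str(row["source"]).strip(),
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from None
    return records


# ---------------------------------------------------------------------------
# harmonization
# ---------------------------------------------------------------------------

def harmonize(
    model: ScoringModel,
    freqs: FrequencyTable,
    palindromic_policy: str = "keep",
) -> tuple[ScoringModel, FrequencyTable, HarmonizationReport]:
    """Reconcile a scoring model with a frequency table.

    Each model variant receives exactly one action:

    * ``excluded_no_rsid`` — no rsID, cannot be matched to the table;
    * ``excluded_missing`` — rsID absent from the table;
    * ``matched`` — table frequency already refers to the effect allele
      (or carries no allele annotation, in which case it is trusted);
    * ``strand_flipped`` — table allele is the strand complement of the
      effect allele: alleles are complemented, the frequency is unchanged;
    * ``allele_swapped`` — table allele is the other allele (possibly on
      the opposite strand): the frequency becomes ``1 - f``;
    * ``excluded_palindromic`` — strand-ambiguous A/T or C/G variant under
      ``palindromic_policy="drop"``; the default ``"keep"`` retains it with
      a warning.

    Returns the surviving model and a frequency table restricted to the
    surviving variants, both in scoring-model order, plus the report.
    """
    if palindromic_policy not in ("keep", "drop"):
        raise ValidationError(f"unknown palindromic policy {palindromic_policy!r}")

    actions: dict[str, str] = {}
    surviving: list[VariantWeight] = []
    columns: list[np.ndarray] = []
    for variant in model.variants:
        label = variant.label
        if variant.rsid is None:
            actions[label] = "excluded_no_rsid"
            continue
        if variant.rsid not in freqs.variants:
            actions[label] = "excluded_missing"
            continue
        if variant.is_palindromic:
            if palindromic_policy == "drop":
                actions[label] = "excluded_palindromic"
                continue
            warnings.warn(
                f"palindromic variant {label} kept as reported; strand cannot "
                "be verified from alleles alone",
                stacklevel=2,
            )
        j = freqs.variants.index(variant.rsid)
        col = freqs.freq[:, j].copy()
        table_allele = freqs.alleles.get(variant.rsid)
        action = "matched"
        out_variant = variant
        if table_allele is not None and table_allele != variant.effect_allele:
            if table_allele == _COMPLEMENT[variant.effect_allele] and not variant.is_palindromic:
                action = "strand_flipped"  # same allele, opposite strand
            elif variant.other_allele is not None and table_allele in (
                variant.other_allele,
                _COMPLEMENT[variant.other_allele],
            ):
                action = "allele_swapped"
                col = 1.0 - col
            else:
                raise ValidationError(
                    f"frequency table allele {table_allele} for {label} matches "
                    f"neither the effect allele nor the other allele"
                )
        actions[label] = action
        surviving.append(out_variant)
        columns.append(col)

    if not surviving:
        raise ValidationError("no variants survive harmonization; nothing to score")

    out_model = ScoringModel(
        variants=tuple(surviving), score_id=model.score_id, trait=model.trait
    )
    out_freqs = FrequencyTable(
        populations=freqs.populations,
        variants=tuple(v.rsid for v in surviving),  # type: ignore[misc]
        freq=np.column_stack(columns),
        alleles={v.rsid: v.effect_allele for v in surviving if v.rsid},
        sample_sizes=freqs.sample_sizes,
    )
    return out_model, out_freqs, HarmonizationReport(actions=actions)


# ---------------------------------------------------------------------------
# report writer
# ---------------------------------------------------------------------------

def write_report(report: Mapping, path: str | Path, format: str = "json") -> None:
    """Serialize an analysis report.

    ``json`` writes the nested mapping at full float precision (round-trip
    safe). ``tsv`` writes a flat table; the PRS section becomes one row per
    population, everything else one ``section  key  value`` row.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "json":
        path.write_text(json.dumps(report, indent=2, allow_nan=True) + "\n",
                        encoding="utf-8")
        return
    if format != "tsv":
        raise ValidationError(f"unknown report format {format!r}")
    lines = ["section\tkey\tvalue"]
    for section, payload in report.items():
        if section == "prs" and isinstance(payload, Mapping):
            for pop, entry in payload.items():
                value = entry["prs"] if isinstance(entry, Mapping) else entry
                lines.append(f"prs\t{pop}\t{value!r}")
        else:
            for key, value in _flatten(payload, prefix=""):
                lines.append(f"{section}\t{key}\t{value!r}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def _flatten(obj, prefix: str) -> Iterable[tuple[str, object]]:
    if isinstance(obj, Mapping):
        for key, value in obj.items():
            yield from _flatten(value, f"{prefix}{key}." if prefix else f"{key}.")
    elif isinstance(obj, (list, tuple)):
        for i, value in enumerate(obj):
            yield from _flatten(value, f"{prefix}{i}.")
    else:
        yield prefix.rstrip("."), obj
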