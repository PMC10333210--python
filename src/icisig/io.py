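"""Readers and writers for the tabular formats the pipeline touches.

Expression matrices are tab- or comma-delimited text, genes in rows by
default, with a header row of sample ids.  Phenotype tables carry the
binary response label (pCR / residual disease), the treatment arm used as
the batch label, and an optional treatment tag.  Gene sets use the GMT
format.  Model bundles and configuration are JSON (config alternatively
YAML).

All readers reject malformed input with a typed error rather than
silently coercing.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("icisig")

RESPONDER = "responder"
NON_RESPONDER = "non_responder"
UNKNOWN = "unknown"

#: accepted phenotype response codes -> canonical label
RESPONSE_CODES: Mapping[str, str] = {
    "pcr": RESPONDER,
    "rd": NON_RESPONDER,
    "1": RESPONDER,
    "0": NON_RESPONDER,
    "responder": RESPONDER,
    "non_responder": NON_RESPONDER,
    "nonresponder": NON_RESPONDER,
}


class IcisigError(Exception):
    """Base class for all package errors."""


class FormatError(IcisigError):
    """Malformed input file (ragged rows, bad codes, schema mismatch)."""


class ValidationError(IcisigError):
    """In-memory object violates a structural invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionCohort:
    """A log2-scale expression matrix with per-sample annotations.

    Parameters
    ----------
    genes
        Ordered HGNC-style symbols; uppercased and unique.
    samples
        Ordered sample identifiers; unique.
    values
        ``len(genes) x len(samples)`` float matrix, log2-scale expression.
    response
        Per-sample label, each in ``{responder, non_responder, unknown}``.
    batch
        Per-sample treatment-arm / batch label.
    """

    genes: list[str]
    samples: list[str]
    values: np.ndarray
    response: np.ndarray = None  # type: ignore[assignment]
    batch: np.ndarray = None  # type: ignore[assignment]
    cohort_id: str = ""
    treatment: str = ""

    def __post_init__(self) -> None:
        self.genes = [str(g).upper() for g in self.genes]
        self.samples = [str(s) for s in self.samples]
        self.values = np.asarray(self.values, dtype=float)
        if self.response is None:
            self.response = np.array([UNKNOWN] * len(self.samples), dtype=object)
        else:
            self.response = np.asarray(self.response, dtype=object)
        if self.batch is None:
            self.batch = np.array(["batch0"] * len(self.samples), dtype=object)
        else:
            self.batch = np.asarray(self.batch, dtype=object)
        self.validate()

    def validate(self) -> None:
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        dup = _duplicates(self.genes)
        if dup:
            raise ValidationError(f"duplicate gene symbols: {sorted(dup)[:5]}")
        dup = _duplicates(self.samples)
        if dup:
            raise ValidationError(f"duplicate sample ids: {sorted(dup)[:5]}")
        if np.isnan(self.values).any():
            raise ValidationError("expression matrix contains missing values")
        if len(self.response) != len(self.samples) or len(self.batch) != len(self.samples):
            raise ValidationError("annotation length does not match sample count")
        bad = set(self.response) - {RESPONDER, NON_RESPONDER, UNKNOWN}
        if bad:
            raise ValidationError(f"unrecognized response labels: {sorted(bad)}")

    # -- convenience accessors ------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def X(self) -> np.ndarray:
        """Samples x genes view (the learner orientation)."""
        return self.values.T

    @property
    def y(self) -> np.ndarray:
        """Binary labels: 1 = responder, 0 = non-responder.

        Raises if any sample has an unknown label.
        """
        if UNKNOWN in set(self.response):
            raise ValidationError("cohort contains samples with unknown response")
        return (self.response == RESPONDER).astype(int)

    def gene_index(self, symbols: Sequence[str]) -> np.ndarray:
        pos = {g: i for i, g in enumerate(self.genes)}
        missing = [s for s in symbols if s.upper() not in pos]
        if missing:
            raise ValidationError(f"genes absent from cohort: {missing}")
        return np.array([pos[s.upper()] for s in symbols], dtype=int)

    def subset_genes(self, symbols: Sequence[str]) -> "ExpressionCohort":
        idx = self.gene_index(symbols)
        return ExpressionCohort(
            genes=[self.genes[i] for i in idx],
            samples=list(self.samples),
            values=self.values[idx, :].copy(),
            response=self.response.copy(),
            batch=self.batch.copy(),
            cohort_id=self.cohort_id,
            treatment=self.treatment,
        )

    def subset_samples(self, idx: Sequence[int]) -> "ExpressionCohort":
        idx = np.asarray(idx, dtype=int)
        return ExpressionCohort(
            genes=list(self.genes),
            samples=[self.samples[i] for i in idx],
            values=self.values[:, idx].copy(),
            response=self.response[idx].copy(),
            batch=self.batch[idx].copy(),
            cohort_id=self.cohort_id,
            treatment=self.treatment,
        )

    def copy(self) -> "ExpressionCohort":
        return self.subset_samples(range(self.n_samples))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.samples)


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. T-cell, B-cell, mitotic-rate signatures).

    Singleton sets model single-marker features such as CD274 (PD-L1)
    or PDCD1 (PD-1) expression.
    """

    sets: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, frozenset[str]] = {}
        for name, genes in self.sets.items():
            gs = frozenset(str(g).upper() for g in genes)
            if not gs:
                raise ValidationError(f"gene set {name!r} is empty")
            clean[name] = gs
        self.sets = clean

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[str]:
        return iter(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()


@dataclass
class PipelineConfig:
    """All tunable thresholds of the pipeline in one place.

    Defaults are the published operating point: raw p < 0.05 with
    |Z-ratio| > 1.5 for differential calls, top 500 absolute pan-cancer
    scores as candidate features, a stratified 60/40 train/validation
    split, 1000 elimination iterations dropping 20% of features per
    step, and confidence-score tiers at 0.4 / 0.65.
    """

    p_threshold: float = 0.05
    zratio_threshold: float = 1.5
    screen_top_k: int = 500
    train_fraction: float = 0.6
    n_iterations: int = 1000
    drop_fraction: float = 0.2
    n_trees: int = 500
    tier_low: float = 0.4
    tier_high: float = 0.65
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValidationError("train_fraction must lie strictly in (0, 1)")
        if not 0 <= self.tier_low < self.tier_high <= 1:
            raise ValidationError("tier cutoffs must satisfy 0 <= low < high <= 1")
        if self.n_iterations < 1:
            raise ValidationError("n_iterations must be >= 1")
        if not 0 < self.drop_fraction < 1:
            raise ValidationError("drop_fraction must lie strictly in (0, 1)")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in {".yaml", ".yml"}:
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls(**data)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        data = dataclasses.asdict(self)
        if path.suffix.lower() in {".yaml", ".yml"}:
            import yaml

            path.write_text(yaml.safe_dump(data))
        else:
            path.write_text(json.dumps(data, indent=2))


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _duplicates(items: Sequence[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for x in items:
        if x in seen:
            dup.add(x)
        seen.add(x)
    return dup


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression(
    path: str | Path,
    orientation: str = "genes_in_rows",
    impute_missing: bool = False,
) -> ExpressionCohort:
    """Read a delimited expression matrix into an :class:`ExpressionCohort`.

    The first column holds row identifiers and a header row is required.
    ``orientation`` is ``genes_in_rows`` (default) or ``samples_in_rows``.
    Missing values are rejected unless ``impute_missing`` requests
    per-gene mean imputation.  Phenotype annotations are attached
    separately with :func:`attach_phenotype`.
    """
    path = Path(path)
    if orientation not in {"genes_in_rows", "samples_in_rows"}:
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0,
                     float_precision="round_trip")
    if orientation == "samples_in_rows":
        df = df.T
    df.index = df.index.astype(str).str.upper()
    dup = _duplicates(list(df.index))
    if dup:
        raise FormatError(f"duplicate gene symbols in {path.name}: {sorted(dup)[:5]}")
    dup = _duplicates(list(df.columns.astype(str)))
    if dup:
        raise FormatError(f"duplicate sample ids in {path.name}: {sorted(dup)[:5]}")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"non-numeric expression value in {path.name}: {exc}") from exc
    if np.isnan(values).any():
        if not impute_missing:
            raise FormatError(
                f"missing values in {path.name}; pass impute_missing=True "
                "for per-gene mean imputation"
            )
        row_mean = np.nanmean(values, axis=1)
        if np.isnan(row_mean).any():
            raise FormatError(f"gene with all values missing in {path.name}")
        nan_r, nan_c = np.nonzero(np.isnan(values))
        values[nan_r, nan_c] = row_mean[nan_r]
        logger.warning("imputed %d missing values with per-gene means", len(nan_r))
    return ExpressionCohort(
        genes=list(df.index),
        samples=[str(c) for c in df.columns],
        values=values,
        cohort_id=path.stem,
    )


def write_expression(cohort: ExpressionCohort, path: str | Path) -> None:
    path = Path(path)
    # %.17g keeps the write -> read round trip bit-exact for float64
    cohort.to_frame().to_csv(path, sep=_sep_for(path), float_format="%.17g")


def read_phenotype(path: str | Path) -> pd.DataFrame:
    """Read per-sample annotations: ``sample_id``, ``response``, ``batch``.

    Response codes pCR/RD (any case) or 1/0 are mapped to
    responder / non_responder; anything else is a :class:`FormatError`.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    required = {"sample_id", "response", "batch"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"phenotype file missing columns: {sorted(missing)}")
    dup = _duplicates(list(df["sample_id"]))
    if dup:
        raise FormatError(f"duplicate sample ids in phenotype: {sorted(dup)[:5]}")

    def _map(code: str) -> str:
        key = str(code).strip().lower()
        if key not in RESPONSE_CODES:
            raise FormatError(f"unrecognized response code {code!r}")
        return RESPONSE_CODES[key]

    df = df.copy()
    df["response"] = df["response"].map(_map)
    if "treatment" not in df.columns:
        df["treatment"] = ""
    return df.set_index("sample_id")


def write_phenotype(cohort: ExpressionCohort, path: str | Path) -> None:
    path = Path(path)
    inv = {RESPONDER: "pCR", NON_RESPONDER: "RD", UNKNOWN: "NA"}
    df = pd.DataFrame(
        {
            "sample_id": cohort.samples,
            "response": [inv[r] for r in cohort.response],
            "batch": cohort.batch,
            "treatment": cohort.treatment,
        }
    )
    df.to_csv(path, sep=_sep_for(path), index=False)


def attach_phenotype(cohort: ExpressionCohort, phenotype: pd.DataFrame) -> ExpressionCohort:
    """Join phenotype annotations onto an expression cohort by sample id."""
    missing = [s for s in cohort.samples if s not in phenotype.index]
    if missing:
        raise FormatError(f"samples absent from phenotype table: {missing[:5]}")
    sub = phenotype.loc[cohort.samples]
    out = cohort.copy()
    out.response = sub["response"].to_numpy(dtype=object)
    out.batch = sub["batch"].to_numpy(dtype=object)
    if "treatment" in sub.columns:
        uniq = sorted(set(sub["treatment"].astype(str)))
        out.treatment = uniq[0] if len(uniq) == 1 else "+".join(uniq)
    out.validate()
    return out


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: ``name TAB description TAB gene1 TAB gene2 ...``."""
    path = Path(path)
    sets: dict[str, frozenset[str]] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path.name}:{lineno}: GMT line has fewer than 3 fields")
        name = fields[0]
        if name in sets:
            raise FormatError(f"{path.name}:{lineno}: duplicate set name {name!r}")
        sets[name] = frozenset(g.upper() for g in fields[2:] if g)
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = [
        "\t".join([name, "na", *sorted(genes)])
        for name, genes in collection.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


# -- model bundles ----------------------------------------------------------


def save_model(model, path: str | Path) -> None:
    """Serialize a trained signature model to a JSON bundle.

    The bundle stores the normalized training matrix, labels, seed and
    forest settings; :func:`load_model` refits deterministically, so the
    reloaded model produces bit-identical scores.
    """
    Path(path).write_text(json.dumps(model.to_dict()))


def load_model(path: str | Path):
    from .model import SignatureModel

    try:
        data = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"corrupted model bundle: {exc}") from exc
    return SignatureModel.from_dict(data)
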