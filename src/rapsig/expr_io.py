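"""Data model and on-disk formats for expression matrices, annotations and signatures.

All files are plain tab-delimited text so fixtures stay diff-able.  An
expression matrix is stored with probe identifiers in the first column and
sample identifiers in the header row; a fitted drug-response signature is a
probe table (probe_id, gene_symbol, weight) plus a JSON sidecar holding the
regression posterior and the reference statistics needed to score new
samples.  Readers validate invariants and reject bad input rather than
silently repairing it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Scale",
    "ExpressionMatrix",
    "ProbitPosterior",
    "DrugResponseSignature",
    "CLASS_LABELS",
    "SUBTYPES",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_annotations",
    "write_annotations",
    "read_probe_gene_map",
    "write_probe_gene_map",
    "read_signature",
    "write_signature",
    "read_predictions",
    "write_predictions",
]

CLASS_LABELS = ("treated", "control", "unknown")
SUBTYPES = (
    "basal-like",
    "HER2-overexpressing",
    "luminal A",
    "luminal B",
    "normal-like",
    "none",
)


class Scale(str, Enum):
    """Scale of stored intensities: raw (MAS5-style) or log2."""

    linear = "linear"
    log2 = "log2"


def _check_unique(ids, what: str) -> None:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dup = idx[idx.duplicated()][0]
        raise ValueError(f"duplicate {what} id: {dup!r}")


@dataclass
class ExpressionMatrix:
    """Probes x samples intensity matrix with a declared scale.

    ``data`` is a DataFrame indexed by probe id with sample ids as columns.
    ``history`` accumulates the normalization steps applied, in order.
    """

    data: pd.DataFrame
    scale: Scale = Scale.linear
    history: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.scale = Scale(self.scale)
        _check_unique(self.data.index, "probe")
        _check_unique(self.data.columns, "sample")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if not np.all(np.isfinite(values)):
            r, c = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite value at probe {self.data.index[r]!r}, "
                f"sample {self.data.columns[c]!r}"
            )

    @property
    def probe_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def with_values(self, values: np.ndarray, scale: Scale | None = None,
                    record=None) -> "ExpressionMatrix":
        """New matrix with the same labels, updated values and history."""
        out = ExpressionMatrix(
            pd.DataFrame(values, index=self.data.index, columns=self.data.columns),
            scale=self.scale if scale is None else scale,
            history=list(self.history),
        )
        if record is not None:
            out.history.append(record)
        return out


@dataclass
class ProbitPosterior:
    """Posterior draws of (intercept, slope) from the binary-regression fit.

    ``draws`` has shape (n_draws, 2).  ``link`` is "probit" for the Gibbs
    sampler and "logit" for the maximum-likelihood logistic fallback (which
    stores a single row of coefficients).
    """

    draws: np.ndarray
    link: str = "probit"

    def __post_init__(self) -> None:
        self.draws = np.atleast_2d(np.asarray(self.draws, dtype=float))
        if self.draws.shape[1] != 2:
            raise ValueError("draws must have two columns (intercept, slope)")
        if self.link not in ("probit", "logit"):
            raise ValueError(f"unknown link {self.link!r}")

    def to_dict(self) -> dict:
        return {"link": self.link, "draws": self.draws.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "ProbitPosterior":
        return cls(np.asarray(d["draws"], dtype=float), link=d["link"])


@dataclass
class DrugResponseSignature:
    """A fitted drug-response signature.

    The probe table (ids, gene symbols, unit-norm first-principal-component
    weights) is what the signature *is*; the remaining fields are the fit
    state required to score new samples: the metagene scores and labels of
    the training samples, the regression posterior, the sorted reference
    quantiles of the processed training submatrix, and the per-probe
    training means/SDs used for standardization.
    """

    probe_ids: np.ndarray
    gene_symbols: np.ndarray
    weights: np.ndarray
    train_scores: np.ndarray
    train_labels: np.ndarray  # boolean, True = treated
    regression_state: ProbitPosterior
    reference_quantiles: np.ndarray
    train_row_means: np.ndarray
    train_row_sds: np.ndarray

    def __post_init__(self) -> None:
        self.probe_ids = np.asarray(self.probe_ids, dtype=object)
        self.gene_symbols = np.asarray(self.gene_symbols, dtype=object)
        for name in ("weights", "train_scores", "reference_quantiles",
                     "train_row_means", "train_row_sds"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.train_labels = np.asarray(self.train_labels, dtype=bool)
        k = len(self.probe_ids)
        if not (len(self.gene_symbols) == len(self.weights) == k):
            raise ValueError("probe_ids, gene_symbols and weights must have equal length")
        if len(self.train_row_means) != k or len(self.train_row_sds) != k:
            raise ValueError("training row statistics must match signature length")
        if len(self.train_scores) != len(self.train_labels):
            raise ValueError("train_scores and train_labels must have equal length")
        _check_unique(self.probe_ids, "probe")
        norm = float(np.linalg.norm(self.weights))
        if not np.isclose(norm, 1.0, atol=1e-6):
            raise ValueError(f"weight vector must have unit norm, got {norm:.6g}")

    @property
    def k(self) -> int:
        return len(self.probe_ids)


# ---------------------------------------------------------------------------
# expression matrices

def read_expression_matrix(path, scale: Scale | str) -> ExpressionMatrix:
    """Read a tab-delimited probes x samples matrix.

    The first column holds probe ids and the header row sample ids.  A
    two-line GCT-style preamble (``#1.2`` and a dimensions line) is skipped
    if present.  Duplicate ids and non-numeric cells are rejected with the
    offending coordinates.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#1.2"):
            skip = 2
            fh.readline()
            header = fh.readline()
        else:
            skip = 0
            header = first
    # check the raw header: pandas would silently mangle duplicate sample ids
    _check_unique(header.rstrip("\n").split("\t")[1:], "sample")
    df = pd.read_csv(path, sep="\t", index_col=0, skiprows=skip, dtype=str)
    _check_unique(df.index, "probe")
    try:
        values = df.astype(float)
    except ValueError:
        for col in df.columns:
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            if bad.any():
                probe = df.index[bad][0]
                raise ValueError(
                    f"non-numeric value {df.loc[probe, col]!r} at probe "
                    f"{probe!r}, sample {col!r} in {path}"
                ) from None
        raise
    return ExpressionMatrix(values, scale=Scale(scale))


def write_expression_matrix(m: ExpressionMatrix, path) -> None:
    df = m.data.copy()
    df.index.name = "probe_id"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# annotations and probe->gene maps

_ANN_COLS = ["sample_id", "class_label", "subtype", "study_id"]


def read_annotations(path) -> pd.DataFrame:
    """Read a sample annotation table (sample_id, class_label, subtype, study_id)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _ANN_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation file missing columns: {missing}")
    _check_unique(df["sample_id"], "sample")
    bad = set(df["class_label"]) - set(CLASS_LABELS)
    if bad:
        raise ValueError(f"unknown class labels: {sorted(bad)}")
    bad = set(df["subtype"]) - set(SUBTYPES)
    if bad:
        raise ValueError(f"unknown subtypes: {sorted(bad)}")
    return df[_ANN_COLS]


def write_annotations(ann: pd.DataFrame, path) -> None:
    ann[_ANN_COLS].to_csv(path, sep="\t", index=False)


def read_probe_gene_map(path) -> pd.Series:
    """Read a probe_id -> gene_symbol map; probe ids must be unique."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"probe_id", "gene_symbol"} <= set(df.columns):
        raise ValueError("probe map needs columns probe_id, gene_symbol")
    _check_unique(df["probe_id"], "probe")
    return pd.Series(df["gene_symbol"].to_numpy(), index=df["probe_id"].to_numpy(),
                     name="gene_symbol")


def write_probe_gene_map(mapping: pd.Series, path) -> None:
    pd.DataFrame({"probe_id": mapping.index, "gene_symbol": mapping.to_numpy()}).to_csv(
        path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# signatures

def _sidecar_path(tsv_path: Path) -> Path:
    return tsv_path.with_suffix(tsv_path.suffix + ".state.json")


def write_signature(sig: DrugResponseSignature, path) -> None:
    """Write the probe table to ``path`` and the fit state to a JSON sidecar.

    Floats are serialized at repr precision so write -> read is exact.
    """
    path = Path(path)
    table = pd.DataFrame({
        "probe_id": sig.probe_ids,
        "gene_symbol": sig.gene_symbols,
        "weight": [repr(float(w)) for w in sig.weights],
    })
    table.to_csv(path, sep="\t", index=False)
    state = {
        "train_scores": sig.train_scores.tolist(),
        "train_labels": sig.train_labels.astype(int).tolist(),
        "regression_state": sig.regression_state.to_dict(),
        "reference_quantiles": sig.reference_quantiles.tolist(),
        "train_row_means": sig.train_row_means.tolist(),
        "train_row_sds": sig.train_row_sds.tolist(),
    }
    with open(_sidecar_path(path), "w") as fh:
        json.dump(state, fh)


def read_signature(path) -> DrugResponseSignature:
    path = Path(path)
    table = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "gene_symbol": str})
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(
            f"signature sidecar {sidecar} is missing; the signature is not "
            "applicable for prediction without its fit state")
    with open(sidecar) as fh:
        state = json.load(fh)
    return DrugResponseSignature(
        probe_ids=table["probe_id"].to_numpy(),
        gene_symbols=table["gene_symbol"].to_numpy(),
        weights=table["weight"].astype(float).to_numpy(),
        train_scores=np.asarray(state["train_scores"]),
        train_labels=np.asarray(state["train_labels"], dtype=bool),
        regression_state=ProbitPosterior.from_dict(state["regression_state"]),
        reference_quantiles=np.asarray(state["reference_quantiles"]),
        train_row_means=np.asarray(state["train_row_means"]),
        train_row_sds=np.asarray(state["train_row_sds"]),
    )


# ---------------------------------------------------------------------------
# predictions

_PRED_COLS = ["sample_id", "score", "p_treated", "sensitivity", "call"]


def write_predictions(preds: pd.DataFrame, path) -> None:
    preds[_PRED_COLS].to_csv(path, sep="\t", index=False)


def read_predictions(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "call": str})
    missing = [c for c in _PRED_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"prediction file missing columns: {missing}")
    return df
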