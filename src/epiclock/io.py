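"""Readers, writers and core containers for methylation data and clocks.

All on-disk formats are tab-delimited text.  Every writer prepends a single
provenance comment line of the form ``#md5:<digest> rows:<R> cols:<C>`` so
that readers can detect silently truncated or corrupted files; readers
verify both the shape and the digest when the line is present.

The canonical in-memory orientation is samples-as-rows.  Files written with
probes as rows can be ingested with ``read_matrix(..., transpose=True)``.
"""

from __future__ import annotations

import hashlib
import io as _io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger("epiclock")

#: float format used by all writers; round-trips IEEE doubles exactly.
FLOAT_FMT = "%.17g"

#: the five measured white-blood-cell types, in conventional order.
WBC_COLUMNS = ("basophils", "eosinophils", "monocytes", "lymphocytes", "neutrophils")

#: categorical technical covariates recorded for each sample.
TECHNICAL_COLUMNS = ("plate", "array", "position", "hyb_date")

#: reserved probe id for the intercept row of a coefficient file.
INTERCEPT_ID = "(Intercept)"


class DataFormatError(ValueError):
    """Raised when an on-disk file violates the format contract."""


# ---------------------------------------------------------------------------
# transforms (shared by clock training and prediction)
# ---------------------------------------------------------------------------

TRANSFORM_KINDS = ("beta", "power", "mvalue", "arcsine", "log")


@dataclass(frozen=True)
class TransformSpec:
    """A per-value transformation of methylation beta values.

    kind
        one of ``beta`` (identity), ``power`` (beta**lam), ``mvalue``
        (log2(b/(1-b))), ``arcsine`` (asin(sqrt(b))) or ``log`` (natural
        log).  M-value and log transforms clip to ``[eps, 1-eps]`` first.
    lam
        exponent for the power transform; the conventional search grid is
        0.1 to 2 in steps of 0.05.
    eps
        clipping bound protecting the unbounded transforms near 0 and 1.
    """

    kind: str = "beta"
    lam: float = 1.0
    eps: float = 1e-3

    def __post_init__(self):
        if self.kind not in TRANSFORM_KINDS:
            raise ValueError(f"unknown transform kind {self.kind!r}")
        if self.kind == "power" and not (0.1 - 1e-12 <= self.lam <= 2 + 1e-12):
            raise ValueError(f"power exponent {self.lam} outside [0.1, 2]")
        if not (0 < self.eps < 0.5):
            raise ValueError("eps must lie in (0, 0.5)")

    def apply(self, values):
        """Apply the transform elementwise to an array/DataFrame of betas."""
        v = values
        if self.kind == "beta":
            return v * 1.0
        if self.kind == "power":
            return v**self.lam
        clipped = np.clip(v, self.eps, 1.0 - self.eps)
        if isinstance(v, pd.DataFrame):
            clipped = pd.DataFrame(clipped, index=v.index, columns=v.columns)
        if self.kind == "mvalue":
            return np.log2(clipped / (1.0 - clipped))
        if self.kind == "arcsine":
            # arcsine needs no clipping: asin(sqrt(.)) is finite on [0,1]
            return np.arcsin(np.sqrt(v))
        if self.kind == "log":
            return np.log(clipped)
        raise AssertionError(self.kind)

    @property
    def tag(self) -> str:
        return f"power:{self.lam:g}" if self.kind == "power" else self.kind

    @classmethod
    def from_tag(cls, tag: str, eps: float = 1e-3) -> "TransformSpec":
        if tag.startswith("power:"):
            return cls("power", float(tag.split(":", 1)[1]), eps)
        return cls(tag, eps=eps)


# ---------------------------------------------------------------------------
# MethylationMatrix
# ---------------------------------------------------------------------------


@dataclass
class MethylationMatrix:
    """Samples x probes beta-value matrix with per-sample cohort labels.

    ``beta`` is a DataFrame indexed by sample id with probe ids as columns;
    values must be finite and within [0, 1].  ``cohort`` is a Series aligned
    to the sample index.
    """

    beta: pd.DataFrame
    cohort: pd.Series | None = None

    def __post_init__(self):
        self.validate()

    # -- basic accessors ----------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.beta.index)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.beta.columns)

    @property
    def n_samples(self) -> int:
        return self.beta.shape[0]

    @property
    def n_probes(self) -> int:
        return self.beta.shape[1]

    def validate(self) -> None:
        b = self.beta
        if b.index.duplicated().any():
            dupes = b.index[b.index.duplicated()].tolist()[:3]
            raise DataFormatError(f"duplicate sample ids: {dupes}")
        if b.columns.duplicated().any():
            dupes = b.columns[b.columns.duplicated()].tolist()[:3]
            raise DataFormatError(f"duplicate probe ids: {dupes}")
        vals = b.to_numpy()
        if not np.isfinite(vals).all():
            i, j = np.argwhere(~np.isfinite(vals))[0]
            raise DataFormatError(
                f"non-finite beta at sample {b.index[i]!r}, probe {b.columns[j]!r}"
            )
        bad = (vals < 0) | (vals > 1)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise DataFormatError(
                f"beta value {vals[i, j]} out of [0,1] at sample "
                f"{b.index[i]!r}, probe {b.columns[j]!r}"
            )
        if self.cohort is not None:
            self.cohort = pd.Series(self.cohort).reindex(b.index)
            if self.cohort.isna().any():
                missing = self.cohort.index[self.cohort.isna()].tolist()[:3]
                raise DataFormatError(f"samples missing a cohort label: {missing}")

    def subset_samples(self, sample_ids: Iterable[str]) -> "MethylationMatrix":
        ids = list(sample_ids)
        cohort = self.cohort.loc[ids] if self.cohort is not None else None
        return MethylationMatrix(self.beta.loc[ids], cohort)

    def subset_cohorts(self, cohorts: Iterable[str]) -> "MethylationMatrix":
        if self.cohort is None:
            raise ValueError("matrix carries no cohort labels")
        keep = self.cohort.isin(list(cohorts))
        return MethylationMatrix(self.beta.loc[keep.values], self.cohort[keep])


# ---------------------------------------------------------------------------
# phenotype tables
# ---------------------------------------------------------------------------

PHENOTYPE_REQUIRED = ("sample_id", "age")


def validate_phenotypes(pheno: pd.DataFrame) -> pd.DataFrame:
    """Validate a phenotype table and return it indexed by sample id.

    Required columns: ``sample_id`` and ``age`` (years, finite, > 0).
    Optional columns with enforced contracts: ``surv_time`` (> 0), ``event``
    ({0, 1}), and the five WBC count columns (nonnegative).
    """
    df = pheno.copy()
    if "sample_id" in df.columns:
        df = df.set_index("sample_id")
    if df.index.duplicated().any():
        raise DataFormatError("duplicate sample ids in phenotype table")
    if "age" not in df.columns:
        raise DataFormatError("phenotype table lacks an 'age' column")
    age = df["age"].to_numpy(dtype=float)
    if not np.isfinite(age).all():
        raise DataFormatError("non-finite age values")
    if "surv_time" in df.columns:
        st = df["surv_time"].dropna().to_numpy(dtype=float)
        if (st <= 0).any():
            raise DataFormatError("surv_time must be positive")
    if "event" in df.columns:
        ev = df["event"].dropna().to_numpy(dtype=float)
        if not np.isin(ev, (0, 1)).all():
            raise DataFormatError("event indicator must be 0 or 1")
    for col in WBC_COLUMNS:
        if col in df.columns and (df[col].dropna() < 0).any():
            raise DataFormatError(f"negative cell count in column {col!r}")
    return df


# ---------------------------------------------------------------------------
# AgePredictor
# ---------------------------------------------------------------------------


@dataclass
class AgePredictor:
    """A portable linear age clock.

    Predictions are ``intercept + sum_j w_j * (t(x_j) - mean_j) / sd_j``
    where ``t`` is the stored beta-value transform.  Because weights act on
    the standardized scale, a probe missing from a target matrix can be
    imputed at its training mean and then contributes exactly zero.
    """

    method: str  # "blup" | "enet"
    intercept: float
    weights: pd.Series  # probe id -> weight on the standardized scale
    train_mean: pd.Series
    train_sd: pd.Series
    n_train: int
    transform: TransformSpec = field(default_factory=TransformSpec)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        w = self.weights
        if w.index.duplicated().any():
            raise DataFormatError("duplicate probe ids in predictor weights")
        missing = w.index.difference(self.train_mean.index)
        if len(missing) or len(w.index.difference(self.train_sd.index)):
            raise DataFormatError("every weighted probe needs a training mean and SD")
        self.train_mean = self.train_mean.loc[w.index]
        self.train_sd = self.train_sd.loc[w.index]
        if (self.train_sd <= 0).any():
            bad = self.train_sd.index[self.train_sd <= 0][0]
            raise DataFormatError(f"nonpositive training SD for probe {bad!r}")

    @property
    def n_probes(self) -> int:
        return len(self.weights)

    @property
    def n_selected(self) -> int:
        return int((self.weights != 0).sum())

    def predict(self, matrix: MethylationMatrix, max_missing: float = 0.5) -> pd.Series:
        """Predicted age (years) per sample of ``matrix``."""
        z, report = align(matrix, self, max_missing=max_missing)
        pred = self.intercept + z.to_numpy() @ self.weights.to_numpy()
        return pd.Series(pred, index=z.index, name="predicted_age")


def align(
    matrix: MethylationMatrix,
    predictor: AgePredictor,
    max_missing: float = 0.5,
) -> tuple[pd.DataFrame, dict]:
    """Standardized sample x probe view aligned to a predictor's probes.

    Probes absent from the matrix are imputed at the training mean so they
    contribute zero after centering.  Returns the standardized view and a
    report with the missing fraction and the missing probe ids.
    """
    probes = predictor.weights.index
    present = probes.intersection(matrix.beta.columns)
    missing = probes.difference(matrix.beta.columns)
    frac = len(missing) / max(len(probes), 1)
    if frac > max_missing:
        raise ValueError(
            f"{frac:.1%} of predictor probes missing from matrix "
            f"(threshold {max_missing:.0%})"
        )
    values = predictor.transform.apply(matrix.beta[present])
    full = pd.DataFrame(
        np.broadcast_to(
            predictor.train_mean.to_numpy(), (matrix.n_samples, len(probes))
        ).copy(),
        index=matrix.beta.index,
        columns=probes,
    )
    full[present] = values
    z = (full - predictor.train_mean) / predictor.train_sd
    report = {
        "n_probes": len(probes),
        "n_missing": len(missing),
        "missing_fraction": frac,
        "missing_probes": list(missing),
    }
    if len(missing):
        logger.warning(
            "align: %d/%d predictor probes missing (imputed at training mean)",
            len(missing),
            len(probes),
        )
    return z, report


# ---------------------------------------------------------------------------
# provenance-checked TSV primitives
# ---------------------------------------------------------------------------


def _checksum_line(body: str, nrows: int, ncols: int) -> str:
    digest = hashlib.md5(body.encode()).hexdigest()
    return f"#md5:{digest} rows:{nrows} cols:{ncols}\n"


def _write_table(df: pd.DataFrame, path, index_label: str) -> None:
    buf = _io.StringIO()
    df.to_csv(buf, sep="\t", float_format=FLOAT_FMT, index_label=index_label)
    body = buf.getvalue()
    with open(path, "w") as fh:
        fh.write(_checksum_line(body, df.shape[0], df.shape[1]))
        fh.write(body)


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#md5:"):
            body = fh.read()
            tokens = first[1:].split()
            declared = dict(t.split(":") for t in tokens)
            digest = hashlib.md5(body.encode()).hexdigest()
            if digest != declared["md5"]:
                raise DataFormatError(
                    f"{path}: checksum mismatch — file is truncated or edited"
                )
            df = pd.read_csv(
                _io.StringIO(body), sep="\t", index_col=0,
                float_precision="round_trip",
            )
            if df.shape != (int(declared["rows"]), int(declared["cols"])):
                raise DataFormatError(f"{path}: shape does not match header line")
        else:
            df = pd.read_csv(path, sep="\t", index_col=0, comment="#",
                             float_precision="round_trip")
    return df


# ---------------------------------------------------------------------------
# matrix I/O
# ---------------------------------------------------------------------------


def write_matrix(matrix: MethylationMatrix, path) -> None:
    """Write a beta matrix as TSV: samples as rows, probes as columns.

    The cohort label, when present, is stored as a leading ``cohort``
    column (probe ids never collide with it).
    """
    df = matrix.beta
    if matrix.cohort is not None:
        df = pd.concat([matrix.cohort.rename("cohort"), df], axis=1)
    _write_table(df, path, index_label="sample_id")


def read_matrix(path, transpose: bool = False) -> MethylationMatrix:
    """Read a beta matrix; see :func:`write_matrix` for the layout."""
    df = _read_table(path)
    if transpose:
        df = df.T
    cohort = None
    if "cohort" in df.columns:
        cohort = df.pop("cohort").astype(str)
    try:
        values = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise DataFormatError(f"{path}: non-numeric beta cell ({exc})") from None
    return MethylationMatrix(values, cohort)


def write_phenotypes(pheno: pd.DataFrame, path) -> None:
    df = validate_phenotypes(pheno)
    _write_table(df, path, index_label="sample_id")


def read_phenotypes(path) -> pd.DataFrame:
    return validate_phenotypes(_read_table(path))


# ---------------------------------------------------------------------------
# predictor I/O
# ---------------------------------------------------------------------------


def write_predictor(pred: AgePredictor, path) -> None:
    """Serialize a clock as a coefficient TSV.

    One row per probe (id, weight, train_mean, train_sd) plus a reserved
    ``(Intercept)`` row; method/transform/n_train ride along as key:value
    comment lines after the checksum header.
    """
    df = pd.DataFrame(
        {
            "weight": pred.weights,
            "train_mean": pred.train_mean,
            "train_sd": pred.train_sd,
        }
    )
    intercept = pd.DataFrame(
        {"weight": [pred.intercept], "train_mean": [np.nan], "train_sd": [np.nan]},
        index=[INTERCEPT_ID],
    )
    out = pd.concat([intercept, df])
    buf = _io.StringIO()
    out.to_csv(buf, sep="\t", float_format=FLOAT_FMT, index_label="probe_id")
    body = buf.getvalue()
    with open(path, "w") as fh:
        fh.write(_checksum_line(body, out.shape[0], out.shape[1]))
        fh.write(f"#method:{pred.method}\n")
        fh.write(f"#transform:{pred.transform.tag}\n")
        fh.write(f"#n_train:{pred.n_train}\n")
        fh.write(body)


def read_predictor(path) -> AgePredictor:
    path = Path(path)
    meta: dict[str, str] = {}
    lines = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            lines.append(header)  # file without a provenance line
        for line in fh:
            if line.startswith("#"):
                key, _, val = line[1:].rstrip("\n").partition(":")
                meta[key] = val
            else:
                lines.append(line)
    body = "".join(lines)
    if header.startswith("#md5:"):
        tokens = dict(t.split(":") for t in header[1:].split())
        if hashlib.md5(body.encode()).hexdigest() != tokens["md5"]:
            raise DataFormatError(f"{path}: checksum mismatch — truncated file?")
    df = pd.read_csv(_io.StringIO(body), sep="\t", float_precision="round_trip")
    known = {"probe_id", "weight", "train_mean", "train_sd"}
    extra = [c for c in df.columns if c not in known]
    if extra:
        logger.warning("read_predictor: ignoring unknown columns %s", extra)
    df = df.set_index("probe_id")
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].tolist()[:3]
        raise DataFormatError(f"duplicate probe rows in predictor file: {dupes}")
    if INTERCEPT_ID not in df.index:
        raise DataFormatError(f"predictor file lacks the {INTERCEPT_ID} row")
    intercept = float(df.loc[INTERCEPT_ID, "weight"])
    probes = df.drop(index=INTERCEPT_ID)
    return AgePredictor(
        method=meta.get("method", "unknown"),
        intercept=intercept,
        weights=probes["weight"].astype(float),
        train_mean=probes["train_mean"].astype(float),
        train_sd=probes["train_sd"].astype(float),
        n_train=int(meta.get("n_train", 0)),
        transform=TransformSpec.from_tag(meta.get("transform", "beta")),
        meta=meta,
    )


# ---------------------------------------------------------------------------
# probe sets
# ---------------------------------------------------------------------------


def write_probe_set(probes: Iterable[str], path) -> None:
    with open(path, "w") as fh:
        for p in probes:
            fh.write(f"{p}\n")


def read_probe_set(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip() and not line.startswith("#")]
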