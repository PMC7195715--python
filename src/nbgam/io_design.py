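"""Count-matrix / covariate I/O and the design mini-formula.

The design grammar is deliberately tiny: terms joined by ``+``, a smooth
written ``s(name)`` or ``s(name,k=K)``, everything else a linear term.
An intercept is always present and never written.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """Raised when inputs violate a documented contract."""


@dataclass
class CountMatrix:
    """Gene x sample matrix of non-negative integer read counts."""

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        n_g, n_s = self.counts.shape
        if len(self.gene_ids) != n_g or len(self.sample_ids) != n_s:
            raise ValidationError("ID lists do not match the count matrix shape")
        if len(set(self.gene_ids)) != n_g:
            raise ValidationError("duplicate gene identifiers")
        if len(set(self.sample_ids)) != n_s:
            raise ValidationError("duplicate sample identifiers")
        vals = self.counts
        if not np.issubdtype(vals.dtype, np.integer):
            frac = vals - np.round(vals)
            bad = np.argwhere(np.abs(frac) > 0)
            if bad.size:
                i, j = bad[0]
                raise ValidationError(
                    f"non-integer count {vals[i, j]!r} at gene "
                    f"{self.gene_ids[i]!r}, sample {self.sample_ids[j]!r}"
                )
            self.counts = np.round(vals).astype(np.int64)
        neg = np.argwhere(self.counts < 0)
        if neg.size:
            i, j = neg[0]
            raise ValidationError(
                f"negative count at gene {self.gene_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]


@dataclass
class SampleTable:
    """Per-sample covariates; rows align 1:1 with CountMatrix columns."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.isna().any().any():
            raise ValidationError(
                "missing covariate values; drop those samples before analysis"
            )

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.index]

    def is_continuous(self, name: str) -> bool:
        if name not in self.data.columns:
            raise ValidationError(f"unknown covariate {name!r}")
        return np.issubdtype(self.data[name].dtype, np.number)


@dataclass(frozen=True)
class LinearTerm:
    name: str


@dataclass(frozen=True)
class SmoothTerm:
    name: str
    k: int = 10


@dataclass
class DesignSpec:
    """Ordered model terms; the intercept is implicit."""

    terms: list = field(default_factory=list)

    @property
    def smooth_terms(self) -> list[SmoothTerm]:
        return [t for t in self.terms if isinstance(t, SmoothTerm)]

    @property
    def linear_terms(self) -> list[LinearTerm]:
        return [t for t in self.terms if isinstance(t, LinearTerm)]


_SMOOTH_RE = re.compile(r"^s\(\s*([A-Za-z_]\w*)\s*(?:,\s*k\s*=\s*(\d+)\s*)?\)$")


def parse_design(formula: str, table: SampleTable) -> DesignSpec:
    """Parse ``"s(age) + gender"``-style formulas against a covariate table."""
    if not formula or not formula.strip():
        raise ValidationError("empty design formula")
    terms: list = []
    smoothed: set[str] = set()
    for raw in formula.split("+"):
        tok = raw.strip()
        if not tok:
            raise ValidationError(f"empty term in formula {formula!r}")
        m = _SMOOTH_RE.match(tok)
        if m:
            name, k_str = m.group(1), m.group(2)
            k = int(k_str) if k_str else 10
            if k < 4:
                raise ValidationError(f"smooth basis dimension k={k} < 4 for {name!r}")
            if not table.is_continuous(name):
                raise ValidationError(f"smooth term on categorical covariate {name!r}")
            if name in smoothed:
                raise ValidationError(f"more than one smooth on covariate {name!r}")
            smoothed.add(name)
            terms.append(SmoothTerm(name, k))
        elif re.fullmatch(r"[A-Za-z_]\w*", tok):
            table.is_continuous(tok)  # raises on unknown name
            terms.append(LinearTerm(tok))
        else:
            raise ValidationError(f"cannot parse term {tok!r}")
    return DesignSpec(terms)


def read_counts(path, delimiter: str = "\t") -> CountMatrix:
    """Read a delimited count table: first column gene IDs, header sample IDs."""
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    if df.shape[1] == 0:
        raise ValidationError("count table has no sample columns")
    gene_ids = [str(g) for g in df.index]
    sample_ids = [str(s) for s in df.columns]
    try:
        vals = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValidationError(f"non-numeric entry in count table: {exc}") from exc
    cm = CountMatrix(gene_ids, sample_ids, vals)
    return cm


def write_counts(cm: CountMatrix, path, delimiter: str = "\t") -> None:
    pd.DataFrame(cm.counts, index=cm.gene_ids, columns=cm.sample_ids).to_csv(
        path, sep=delimiter
    )


def read_samples(path, delimiter: str = "\t") -> SampleTable:
    """Read a covariate table; first column holds sample IDs."""
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    df.index = df.index.map(str)
    return SampleTable(df)


# stable output schema: identifier, expression level, per-term statistics,
# information criteria, the linear/nonlinear call and the convergence flag
RESULT_INDEX = "gene_id"


def write_results(results: pd.DataFrame, path, delimiter: str = "\t") -> None:
    """Write a result table as TSV, round-tripping numerics at 10 sig. digits."""
    results.to_csv(path, sep=delimiter, index_label=RESULT_INDEX, float_format="%.10g")


def read_results(path, delimiter: str = "\t") -> pd.DataFrame:
    return pd.read_csv(path, sep=delimiter, index_col=0)
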