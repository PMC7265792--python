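"""Core in-memory containers shared by every pipeline stage.

Expression-like matrices are gene × sample :class:`pandas.DataFrame` objects
wrapped in a validating shell; missing values are explicit ``NaN``, never
silent zeros.  Identifier uniqueness is enforced at construction so every
downstream operation may index by label without ambiguity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """A file does not conform to its declared tabular/GMT format."""


class ValidationError(ValueError):
    """Structurally valid input violating a domain invariant."""


PHENOTYPE_TYPES = frozenset(
    {"survival_time", "survival_event", "two_class", "multi_class", "continuous", "ordinal"}
)


def _check_unique(labels: Sequence[str], what: str) -> None:
    seen: Set[str] = set()
    for lab in labels:
        if lab in seen:
            raise ValidationError(f"duplicate {what} identifier: {lab!r}")
        seen.add(lab)


@dataclass
class ExpressionMatrix:
    """A genes × samples real-valued matrix (log-scale expression or an
    analogous copy-number / methylation layer).

    Parameters
    ----------
    data
        DataFrame indexed by gene id with sample ids as columns.  Values are
        floats; ``NaN`` marks missing measurements.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            raise TypeError("ExpressionMatrix.data must be a pandas DataFrame")
        _check_unique(list(self.data.index), "gene")
        _check_unique(list(self.data.columns), "sample")
        try:
            self.data = self.data.astype(float)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"non-numeric expression values: {exc}") from exc
        self.data.index = self.data.index.astype(str)
        self.data.columns = self.data.columns.astype(str)
        self.data.index.name = None
        self.data.columns.name = None

    @property
    def gene_ids(self) -> List[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> List[str]:
        return list(self.data.columns)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(genes)])

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data[list(samples)])

    def standardized(self, ddof: int = 1) -> pd.DataFrame:
        """Per-gene z-scores across samples (NaN for zero-variance genes)."""
        mat = self.data
        mu = mat.mean(axis=1)
        sd = mat.std(axis=1, ddof=ddof)
        z = mat.sub(mu, axis=0).div(sd.replace(0.0, np.nan), axis=0)
        return z


@dataclass
class OmicsBundle:
    """Expression plus optional copy-number and methylation layers of one cohort."""

    expression: ExpressionMatrix
    cnv: Optional[ExpressionMatrix] = None
    methylation: Optional[ExpressionMatrix] = None
    cohort_name: str = "cohort"

    def __post_init__(self) -> None:
        for name, layer in (("cnv", self.cnv), ("methylation", self.methylation)):
            if layer is None:
                continue
            shared = set(layer.sample_ids) & set(self.expression.sample_ids)
            if not shared:
                raise ValidationError(
                    f"{name} layer shares no samples with the expression matrix"
                )


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics): name -> (description, member genes)."""

    sets: Dict[str, Tuple[str, List[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (_desc, genes) in self.sets.items():
            if not genes:
                raise ValidationError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def genes(self, name: str) -> List[str]:
        return self.sets[name][1]

    def description(self, name: str) -> str:
        return self.sets[name][0]

    def names(self) -> List[str]:
        return list(self.sets)


@dataclass
class PhenotypeTable:
    """Per-sample phenotypes with a declared statistical type per column.

    ``schema`` maps column name to one of ``survival_time``, ``survival_event``,
    ``two_class``, ``multi_class``, ``continuous``, ``ordinal``.  Missing
    observations are ``NaN`` (numeric) or ``None``/``NaN`` (categorical).
    """

    data: pd.DataFrame  # indexed by sample id
    schema: Dict[str, str]

    def __post_init__(self) -> None:
        _check_unique(list(self.data.index), "sample")
        self.data.index = self.data.index.astype(str)
        for col, typ in self.schema.items():
            if typ not in PHENOTYPE_TYPES:
                raise ValidationError(f"unknown phenotype type {typ!r} for column {col!r}")
            if col not in self.data.columns:
                raise ValidationError(f"schema names a missing column: {col!r}")
            values = self.data[col]
            if typ in ("survival_time", "survival_event", "continuous", "ordinal"):
                try:
                    numeric = pd.to_numeric(values, errors="raise")
                except (TypeError, ValueError) as exc:
                    raise ValidationError(f"column {col!r} ({typ}) is not numeric") from exc
                self.data[col] = numeric.astype(float)
                if typ == "survival_time" and (numeric.dropna() < 0).any():
                    raise ValidationError(f"negative survival_time in column {col!r}")
                if typ == "survival_event":
                    observed = set(numeric.dropna().unique())
                    if not observed <= {0.0, 1.0}:
                        raise ValidationError(
                            f"survival_event column {col!r} has values outside {{0,1}}: "
                            f"{sorted(observed - {0.0, 1.0})}"
                        )
            elif typ == "two_class":
                levels = values.dropna().unique()
                if len(levels) > 2:
                    raise ValidationError(
                        f"two_class column {col!r} has {len(levels)} observed levels; "
                        "declare it multi_class instead"
                    )

    @property
    def sample_ids(self) -> List[str]:
        return list(self.data.index)

    def column(self, name: str) -> pd.Series:
        return self.data[name]


@dataclass
class DriverCatalog:
    """Candidate driver genes with per-gene provenance tags.

    provenance values are subsets of {"user_list", "cnv_driven", "met_driven"};
    ``direction`` optionally records "hyper"/"hypo" for methylation-driven genes.
    """

    driver_ids: List[str]
    provenance: Dict[str, Set[str]] = field(default_factory=dict)
    direction: Dict[str, Optional[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_unique(self.driver_ids, "driver")
        for gene in self.driver_ids:
            tags = self.provenance.get(gene)
            if not tags:
                raise ValidationError(f"driver {gene!r} has empty provenance")

    def __len__(self) -> int:
        return len(self.driver_ids)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "gene": g,
                "tags": ",".join(sorted(self.provenance[g])),
                "direction": self.direction.get(g) or "",
            }
            for g in self.driver_ids
        ]
        return pd.DataFrame(rows, columns=["gene", "tags", "direction"])


@dataclass
class RegulatoryProgram:
    """Sparse signed linear model of a module's mean expression over drivers.

    ``weights`` holds only nonzero coefficients.  ``fit_r2`` is the training
    R² clipped to [0, 1]; the raw (possibly negative) value is kept in
    ``raw_r2``.
    """

    weights: Dict[str, float]
    intercept: float = 0.0
    fit_r2: float = 0.0
    raw_r2: float = 0.0

    def __post_init__(self) -> None:
        self.weights = {d: float(w) for d, w in self.weights.items() if w != 0.0}
        self.fit_r2 = float(min(1.0, max(0.0, self.fit_r2)))

    def predict(self, drivers_std: pd.DataFrame) -> np.ndarray:
        """Predicted per-sample profile from standardized driver rows
        (genes × samples)."""
        pred = np.full(drivers_std.shape[1], self.intercept, dtype=float)
        for driver, w in self.weights.items():
            if driver in drivers_std.index:
                pred = pred + w * drivers_std.loc[driver].to_numpy()
        return pred


@dataclass
class Module:
    """One regulatory module: a target-gene set plus its fitted program."""

    module_id: int
    target_ids: List[str]
    program: RegulatoryProgram

    def __post_init__(self) -> None:
        if self.module_id < 1:
            raise ValidationError("module_id must be >= 1")
        _check_unique(self.target_ids, "target")


@dataclass
class ModuleNetwork:
    """All modules of one cohort plus the assignment map and run metadata."""

    cohort_name: str
    modules: List[Module]
    assignment: Dict[str, int]
    n_iterations: int = 0
    converged: bool = True
    reassignment_trace: List[float] = field(default_factory=list)
    settings: Dict[str, object] = field(default_factory=dict)
    is_guide: bool = False

    def __post_init__(self) -> None:
        ids = [m.module_id for m in self.modules]
        _check_unique([str(i) for i in ids], "module")
        known = set(ids)
        for gene, mid in self.assignment.items():
            if mid not in known:
                raise ValidationError(f"gene {gene!r} assigned to unknown module {mid}")

    @property
    def module_ids(self) -> List[int]:
        return [m.module_id for m in self.modules]

    def module(self, module_id: int) -> Module:
        for m in self.modules:
            if m.module_id == module_id:
                return m
        raise KeyError(module_id)

    @property
    def target_universe(self) -> Set[str]:
        return set(self.assignment)


@dataclass(frozen=True, order=True)
class ModuleRef:
    """(cohort, module_id) handle used by the cross-cohort module map."""

    cohort: str
    module_id: int

    def __str__(self) -> str:  # used in output tables / graph node ids
        return f"{self.cohort}:M{self.module_id}"


@dataclass
class ModuleMapEdge:
    """Significance-weighted overlap link between modules of two cohorts."""

    module_a: ModuleRef
    module_b: ModuleRef
    overlap_count: int
    p_value: float
    neg_log10_p: float
    fdr: float = float("nan")

    def __post_init__(self) -> None:
        if self.module_a.cohort == self.module_b.cohort:
            raise ValidationError("module map edges connect different cohorts")


@dataclass
class Community:
    """A connected group of >=2 modules from the filtered module map."""

    community_id: int
    members: List[ModuleRef]
    edges: List[ModuleMapEdge] = field(default_factory=list)

    @property
    def cohorts(self) -> Set[str]:
        return {m.cohort for m in self.members}


@dataclass
class AssociationResult:
    """Outcome of one module/community × phenotype statistical test."""

    module_ref: object  # ModuleRef or community id string
    phenotype: str
    test: str
    statistic: float = float("nan")
    effect_direction: int = 0
    p_value: float = float("nan")
    fdr: float = float("nan")
    n_used: int = 0
    note: str = ""

    @property
    def testable(self) -> bool:
        return np.isfinite(self.p_value)
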