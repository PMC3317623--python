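"""Stream-community ecology: occupancy, Ivlev electivity, PCA and ANOVA.

Microhabitats are the eight velocity x substrate strata of a stream section
({fast, slow} x {rock, gravel, leaves, sand}).  Habitat selection is measured
by Ivlev's electivity index

    E = (r - p) / (r + p)

where ``r`` is the proportion of specimens of a species found in a
microhabitat and ``p`` the proportion of that microhabitat available in the
stream; E ranges from -1 (complete avoidance) to +1 (exclusive use) and is
undefined where r + p = 0.  E is computed per stream, and streams act as
replicates in a two-factor (microhabitat + species) ANOVA without interaction,
with per-microhabitat subset ANOVAs standing in for the interaction.  Breeding
site choice across streams is summarised by a PCA on the correlation matrix of
the habitat variables, with species incidence overlaid as supplementary
variables that never influence the decomposition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MICROHABITATS",
    "MicrohabitatTable",
    "ElectivityResult",
    "PcaResult",
    "AnovaResult",
    "electivity",
    "electivity_table",
    "filter_streams",
    "occupancy_summary",
    "boxcox_transform",
    "habitat_pca",
    "electivity_anova",
]

VELOCITIES = ("fast", "slow")
SUBSTRATES = ("rock", "gravel", "leaves", "sand")
MICROHABITATS = tuple(f"{v}_{s}" for v in VELOCITIES for s in SUBSTRATES)


@dataclass
class MicrohabitatTable:
    """Counts per (stream, species) x microhabitat plus per-stream availability.

    ``counts`` is indexed by a (stream, species) MultiIndex with one column per
    microhabitat; ``availability`` is indexed by stream with the same columns
    and rows summing to 1.
    """

    counts: pd.DataFrame
    availability: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = self.counts.reindex(columns=list(MICROHABITATS)).fillna(0)
        self.availability = self.availability.reindex(columns=list(MICROHABITATS))
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.allclose(self.counts.to_numpy() % 1, 0):
            raise ValueError("counts must be integers")
        self.counts = self.counts.astype(int)
        sums = self.availability.sum(axis=1)
        bad = sums[(sums - 1).abs() > 1e-9]
        if len(bad):
            raise ValueError(
                f"availability must sum to 1 per stream; offending streams: "
                f"{list(bad.index)}"
            )

    @property
    def streams(self) -> list:
        return sorted(self.availability.index)

    @property
    def species(self) -> list:
        return sorted(self.counts.index.get_level_values("species").unique())

    @classmethod
    def from_long(
        cls, counts_long: pd.DataFrame, availability_long: pd.DataFrame
    ) -> "MicrohabitatTable":
        """Build from long-format frames.

        ``counts_long``: columns stream, species, velocity, substrate, count.
        ``availability_long``: stream, velocity, substrate, proportion.
        """
        def _mh(df: pd.DataFrame) -> pd.Series:
            return df["velocity"].astype(str) + "_" + df["substrate"].astype(str)

        c = counts_long.assign(microhabitat=_mh(counts_long)).pivot_table(
            index=["stream", "species"],
            columns="microhabitat",
            values="count",
            aggfunc="sum",
            fill_value=0,
        )
        a = availability_long.assign(
            microhabitat=_mh(availability_long)
        ).pivot_table(
            index="stream", columns="microhabitat", values="proportion"
        ).fillna(0.0)
        return cls(counts=c, availability=a)

    def to_long(self) -> pd.DataFrame:
        long = self.counts.stack().rename("count").reset_index()
        long.columns = ["stream", "species", "microhabitat", "count"]
        parts = long["microhabitat"].str.split("_", n=1, expand=True)
        long["velocity"], long["substrate"] = parts[0], parts[1]
        return long[["stream", "species", "velocity", "substrate", "count"]]


def electivity(r: float, p: float) -> float:
    """Ivlev's E = (r - p)/(r + p); NaN where undefined (r + p = 0)."""
    if r < 0 or p < 0:
        raise ValueError("proportions must be non-negative")
    if r + p == 0:
        return float("nan")
    return (r - p) / (r + p)


@dataclass
class ElectivityResult:
    E: pd.DataFrame       # (stream, species) x microhabitat, NaN = undefined
    r: pd.DataFrame       # use proportions, NaN for empty species-streams
    p: pd.DataFrame       # availability broadcast onto the count rows
    pooled: bool = False


def electivity_table(
    table: MicrohabitatTable, pooled: bool = False
) -> ElectivityResult:
    """E per (stream, species, microhabitat).

    ``r`` is each species' count share within a stream; a species-stream with
    zero specimens yields an all-undefined row.  With ``pooled=True`` counts
    are first summed over streams per species and compared against the mean
    availability of the included streams (secondary mode).
    """
    counts = table.counts
    if pooled:
        pooled_counts = counts.groupby(level="species").sum()
        avail = table.availability.mean(axis=0)
        totals = pooled_counts.sum(axis=1)
        r = pooled_counts.div(totals, axis=0).where(totals > 0)
        p = pd.DataFrame(
            np.tile(avail.to_numpy(), (len(pooled_counts), 1)),
            index=pooled_counts.index,
            columns=pooled_counts.columns,
        )
    else:
        totals = counts.sum(axis=1)
        r = counts.div(totals, axis=0).where(totals > 0)
        p = table.availability.reindex(
            counts.index.get_level_values("stream")
        ).set_axis(counts.index)
    with np.errstate(invalid="ignore", divide="ignore"):
        E = (r - p) / (r + p)
    E = E.where((r + p) > 0)
    return ElectivityResult(E=E, r=r, p=p, pooled=pooled)


def filter_streams(
    table: MicrohabitatTable, species: str, min_specimens: int = 8
) -> MicrohabitatTable:
    """Keep only streams holding >= ``min_specimens`` of ``species``.

    The eight-specimen default guards the electivity analysis against many
    spurious avoidance values arising from sparsely occupied streams.
    """
    if min_specimens < 0:
        raise ValueError("min_specimens must be >= 0")
    totals = (
        table.counts.xs(species, level="species").sum(axis=1)
        if species in table.species
        else pd.Series(dtype=int)
    )
    keep = totals[totals >= min_specimens].index
    if len(keep) == 0:
        warnings.warn(
            f"no stream holds >= {min_specimens} specimens of {species!r}",
            stacklevel=2,
        )
    counts = table.counts[
        table.counts.index.get_level_values("stream").isin(keep)
    ]
    availability = table.availability.loc[table.availability.index.isin(keep)]
    if len(keep) == 0:
        # preserve structure for an empty result
        availability = table.availability.iloc[0:0]
    return MicrohabitatTable(counts=counts, availability=availability)


def occupancy_summary(table: MicrohabitatTable, species: str) -> dict[str, float]:
    """Occupancy of a species over streams: how many streams hold it and with
    how many specimens (mean/min/max over occupied streams)."""
    n_streams = len(table.availability)
    if species in table.species:
        per_stream = table.counts.xs(species, level="species").sum(axis=1)
        occupied = per_stream[per_stream > 0]
    else:
        occupied = pd.Series(dtype=int)
    n_occ = int(len(occupied))
    return {
        "n_streams_occupied": n_occ,
        "n_streams_total": n_streams,
        "fraction_of_streams": n_occ / n_streams if n_streams else float("nan"),
        "mean_specimens": float(occupied.mean()) if n_occ else float("nan"),
        "min_specimens": int(occupied.min()) if n_occ else 0,
        "max_specimens": int(occupied.max()) if n_occ else 0,
    }


def boxcox_transform(
    values: Sequence[float],
) -> tuple[np.ndarray, float, float]:
    """Box-Cox power transform with maximum-likelihood lambda.

    Returns ``(transformed, lambda, offset)``.  Zeros are handled by shifting
    all values by half the smallest positive value (offset recorded); negative
    values are rejected.  A constant vector has no defined transform.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 3:
        raise ValueError("need a 1-D sample of at least 3 values")
    if (x < 0).any():
        raise ValueError("Box-Cox requires non-negative input")
    offset = 0.0
    if (x == 0).any():
        positive = x[x > 0]
        if len(positive) == 0:
            raise ValueError("all values are zero")
        offset = positive.min() / 2.0
        x = x + offset
    if np.ptp(x) == 0:
        raise ValueError("constant vector has no Box-Cox transform")
    transformed, lam = stats.boxcox(x)
    return transformed, float(lam), offset


@dataclass
class PcaResult:
    eigenvalues: np.ndarray
    percent_variance: np.ndarray
    loadings: pd.DataFrame          # variables x PCs, orthonormal eigenvectors
    scores: pd.DataFrame            # streams x PCs
    retained: int
    supplementary: pd.DataFrame = field(default_factory=pd.DataFrame)
    transform_log: dict[str, Optional[float]] = field(default_factory=dict)


def _scree_elbow(eigenvalues: np.ndarray) -> int:
    """Number of components before the largest scree drop.

    Automates the visual scree criterion as the maximum second difference of
    the eigenvalue profile; retains at least one component.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    if len(lam) < 3:
        return 1
    second = lam[:-2] - 2 * lam[1:-1] + lam[2:]   # d2[k] at component k+2
    # retain k components where the drop after component k is steepest
    return int(np.argmax(second)) + 1


def habitat_pca(
    matrix: pd.DataFrame,
    species_incidence: Optional[pd.DataFrame] = None,
    retain: Optional[int] = None,
    boxcox: bool = False,
) -> PcaResult:
    """PCA of stream habitat variables on the correlation matrix.

    Running on the correlation matrix standardises away unequal variances.
    ``retain`` overrides the automated scree-elbow choice.  ``species_incidence``
    (streams x species, boolean presence) is correlated with the retained PC
    scores as supplementary variables (Pearson r and p), never influencing the
    decomposition.  Optional Box-Cox preprocessing symmetrises skewed
    variables; the fitted lambdas are recorded in ``transform_log``.
    """
    if len(matrix) < 3:
        raise ValueError("PCA needs at least 3 streams")
    X = matrix.astype(float).copy()
    if X.isna().any().any():
        raise ValueError("habitat matrix has missing cells")
    transform_log: dict[str, Optional[float]] = {}
    if boxcox:
        for col in X.columns:
            try:
                X[col], lam, _ = boxcox_transform(X[col].to_numpy())
                transform_log[col] = lam
            except ValueError:
                transform_log[col] = None
    sd = X.std(axis=0, ddof=1)
    constant = sd[sd == 0].index.tolist()
    if constant:
        raise ValueError(f"constant variables have no correlation: {constant}")
    Z = (X - X.mean(axis=0)) / sd
    corr = np.corrcoef(Z.to_numpy(), rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    eigval = np.clip(eigval, 0, None)
    if np.min(eigval) < 1e-10:
        warnings.warn("correlation matrix is rank deficient", stacklevel=2)
    percent = eigval / eigval.sum() * 100.0
    pcs = [f"PC{i + 1}" for i in range(len(eigval))]
    # canonical sign: largest-magnitude loading positive
    for j in range(eigvec.shape[1]):
        k = np.argmax(np.abs(eigvec[:, j]))
        if eigvec[k, j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    loadings = pd.DataFrame(eigvec, index=matrix.columns, columns=pcs)
    scores = pd.DataFrame(
        Z.to_numpy() @ eigvec, index=matrix.index, columns=pcs
    )
    retained = retain if retain is not None else _scree_elbow(eigval)
    retained = max(1, min(retained, len(eigval)))

    supplementary = pd.DataFrame()
    if species_incidence is not None:
        rows = []
        incidence = species_incidence.reindex(matrix.index).astype(float)
        for sp in incidence.columns:
            y = incidence[sp]
            if y.nunique() < 2:
                continue  # species everywhere or nowhere: correlation undefined
            for pc in pcs[:retained]:
                r, p = stats.pearsonr(y, scores[pc])
                rows.append(
                    {"species": sp, "pc": pc, "r": r, "p_value": p}
                )
        supplementary = pd.DataFrame(rows)

    return PcaResult(
        eigenvalues=eigval,
        percent_variance=percent,
        loadings=loadings,
        scores=scores,
        retained=retained,
        supplementary=supplementary,
        transform_log=transform_log,
    )


@dataclass
class AnovaResult:
    terms: pd.DataFrame                       # F, df, p per model term
    model_f: float
    model_df: tuple[float, float]
    model_p: float
    n_used: int
    n_dropped: int
    degenerate: bool = False
    subsets: dict[str, "AnovaResult"] = field(default_factory=dict)


def _fit_anova(data: pd.DataFrame, formula: str) -> tuple[pd.DataFrame, object]:
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    model = smf.ols(formula, data=data).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-variance subsets emit RuntimeWarnings
        table = anova_lm(model, typ=2)
    return table, model


def electivity_anova(
    e_long: pd.DataFrame,
    include_interaction: bool = False,
    subset_by_microhabitat: bool = True,
) -> AnovaResult:
    """Two-factor ANOVA of electivity on microhabitat and species.

    ``e_long`` needs columns ``E``, ``species``, ``microhabitat`` (one row per
    stream replicate).  The interaction is omitted by default to avoid
    overparameterisation; per-microhabitat one-factor subset ANOVAs evaluate
    species differences within each microhabitat instead.  Undefined E cells
    (NaN) are dropped and counted.
    """
    required = {"E", "species", "microhabitat"}
    if not required.issubset(e_long.columns):
        raise ValueError(f"e_long must have columns {sorted(required)}")
    data = e_long.dropna(subset=["E"]).copy()
    n_dropped = len(e_long) - len(data)
    n_species = data["species"].nunique()
    n_micro = data["microhabitat"].nunique()

    terms = ["C(microhabitat)"] if n_micro > 1 else []
    if n_species > 1:
        terms.append("C(species)")
    if not terms:
        raise ValueError("need at least two species or two microhabitats")
    if include_interaction and n_species > 1 and n_micro > 1:
        terms.append("C(microhabitat):C(species)")
    formula = "E ~ " + " + ".join(terms)

    n_params = 1 + (n_micro - 1) + (n_species - 1 if n_species > 1 else 0)
    if include_interaction:
        n_params += (n_micro - 1) * (n_species - 1)
    if len(data) <= n_params:
        raise ValueError(
            f"insufficient residual degrees of freedom "
            f"({len(data)} rows for {n_params} parameters)"
        )

    degenerate = bool(np.isclose(data["E"].var(ddof=0), 0.0))
    table, model = _fit_anova(data, formula)
    result = AnovaResult(
        terms=table,
        model_f=float(model.fvalue) if not degenerate else float("nan"),
        model_df=(float(model.df_model), float(model.df_resid)),
        model_p=float(model.f_pvalue) if not degenerate else float("nan"),
        n_used=len(data),
        n_dropped=n_dropped,
        degenerate=degenerate,
    )

    if subset_by_microhabitat and n_species > 1:
        for mh, sub in data.groupby("microhabitat", observed=True):
            if sub["species"].nunique() < 2 or len(sub) < sub["species"].nunique() + 1:
                continue
            sub_degenerate = bool(np.isclose(sub["E"].var(ddof=0), 0.0))
            sub_table, sub_model = _fit_anova(sub, "E ~ C(species)")
            result.subsets[str(mh)] = AnovaResult(
                terms=sub_table,
                model_f=float(sub_model.fvalue) if not sub_degenerate else float("nan"),
                model_df=(float(sub_model.df_model), float(sub_model.df_resid)),
                model_p=float(sub_model.f_pvalue) if not sub_degenerate else float("nan"),
                n_used=len(sub),
                n_dropped=0,
                degenerate=sub_degenerate,
            )
    return result
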