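"""Dendrite-heterogeneity statistics.

Pearson chi-square tests on dendrite x class contingency tables (omnibus,
per-neuron and pairwise with Bonferroni correction), Kruskal-Wallis tests
with Dunn's post hoc on the scalar descriptors, and a shuffle control that
randomly reassigns spines to dendrites while preserving per-dendrite spine
counts.

Chi-square is the plain Pearson form (no Yates correction); a warning flag
is set when any expected count falls below 5.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from spinemorph.io import NeuronDataset

__all__ = [
    "ClassDistribution",
    "StatResult",
    "StatsError",
    "class_count_table",
    "pearson_chi_square",
    "pairwise_dendrite_tests",
    "kruskal_wallis",
    "kruskal_wallis_by_dendrite",
    "dunn_posthoc",
    "shuffle_control",
    "significance_band",
]

SIGNIFICANCE_BANDS = (0.05, 0.01, 0.001)


class StatsError(ValueError):
    pass


@dataclass
class StatResult:
    test: str
    statistic: float
    df: float
    p: float
    p_adjusted: float
    comparison: tuple = ()
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "test": self.test,
            "comparison": "|".join(str(c) for c in self.comparison),
            "statistic": self.statistic,
            "df": self.df,
            "p": self.p,
            "p_adjusted": self.p_adjusted,
            "note": self.note,
        }


def significance_band(p: float, bands=SIGNIFICANCE_BANDS) -> int:
    """Number of display stars for an (adjusted) p-value: 0-3."""
    return int(sum(p <= b for b in bands))


@dataclass
class ClassDistribution:
    """Dendrite x class count table with its identifiers."""

    counts: np.ndarray
    dendrite_ids: list[str]
    class_ids: list[int]
    neuron_by_dendrite: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if np.any(self.counts < 0):
            raise StatsError("counts must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=pd.Index(self.dendrite_ids, name="dendrite_id"),
            columns=[f"class_{c}" for c in self.class_ids],
        )

    def fractions_per_dendrite(self) -> np.ndarray:
        """Class composition of each dendrite (rows sum to 1)."""
        return self.counts / self.counts.sum(axis=1, keepdims=True)

    def fractions_per_class(self) -> np.ndarray:
        """How each class distributes over dendrites (columns sum to 1)."""
        return self.counts / self.counts.sum(axis=0, keepdims=True)


def class_count_table(
    dataset: NeuronDataset,
    labels: dict[str, int],
    scope: str | None = None,
) -> ClassDistribution:
    """Count labelled spines per (dendrite, class).

    ``scope`` restricts to one neuron id; None pools all dendrites.
    Incomplete spines are skipped; a complete spine without a label is an
    error.
    """
    class_ids = sorted(set(labels.values()))
    rows: dict[str, np.ndarray] = {}
    neuron_of: dict[str, str] = {}
    for neuron_id, dendrite_id, ann in dataset.iter_spines():
        if scope is not None and neuron_id != scope:
            continue
        if not ann.complete:
            continue
        if ann.spine_id not in labels:
            raise StatsError(f"spine {ann.spine_id} has no class label")
        row = rows.setdefault(dendrite_id, np.zeros(len(class_ids), dtype=int))
        row[class_ids.index(labels[ann.spine_id])] += 1
        neuron_of[dendrite_id] = neuron_id
    if not rows:
        raise StatsError(f"no labelled spines in scope {scope!r}")
    dendrite_ids = list(rows)
    counts = np.vstack([rows[d] for d in dendrite_ids])
    return ClassDistribution(
        counts=counts,
        dendrite_ids=dendrite_ids,
        class_ids=class_ids,
        neuron_by_dendrite=neuron_of,
    )


def pearson_chi_square(
    table: np.ndarray | ClassDistribution, comparison: tuple = ()
) -> StatResult:
    """Pearson chi-square test of homogeneity on a contingency table.

    All-zero columns are dropped before computing expected counts; a
    zero-margin row (a dendrite with no spines) is an error.
    """
    if isinstance(table, ClassDistribution):
        counts = table.counts
        row_names = table.dendrite_ids
    else:
        counts = np.asarray(table, dtype=float)
        row_names = [str(i) for i in range(len(counts))]
    row_sums = counts.sum(axis=1)
    for name, rs in zip(row_names, row_sums):
        if rs == 0:
            raise StatsError(f"dendrite {name} has a zero row margin")
    counts = counts[:, counts.sum(axis=0) > 0]
    r, c = counts.shape
    if r < 2 or c < 2:
        raise StatsError("need a >= 2x2 table after dropping empty columns")
    total = counts.sum()
    expected = np.outer(counts.sum(axis=1), counts.sum(axis=0)) / total
    chi2 = float(np.sum((counts - expected) ** 2 / expected))
    df = (r - 1) * (c - 1)
    p = float(sps.chi2.sf(chi2, df))
    note = "expected<5" if np.any(expected < 5) else ""
    return StatResult(
        test="pearson_chi_square",
        statistic=chi2,
        df=float(df),
        p=p,
        p_adjusted=p,
        comparison=comparison,
        note=note,
    )


def _bonferroni(p: float, m: int) -> float:
    return min(1.0, p * m)


def pairwise_dendrite_tests(
    table: ClassDistribution | np.ndarray,
    alpha: float = 0.05,
    family_size: int | None = None,
) -> list[StatResult]:
    """Chi-square on every dendrite pair, Bonferroni-corrected.

    The correction family defaults to the set of pairs in ``table``
    (within-neuron or all-dendrite, depending on how the table was scoped);
    pass ``family_size`` to correct against a larger family.  Per-pair
    failures are recorded in the result's note instead of aborting.
    """
    if isinstance(table, np.ndarray):
        table = ClassDistribution(
            counts=table,
            dendrite_ids=[str(i) for i in range(len(table))],
            class_ids=list(range(table.shape[1])),
        )
    n = len(table.dendrite_ids)
    if n < 2:
        raise StatsError("pairwise tests need >= 2 dendrites")
    pairs = list(itertools.combinations(range(n), 2))
    m = family_size if family_size is not None else len(pairs)
    results = []
    for i, j in pairs:
        comp = (table.dendrite_ids[i], table.dendrite_ids[j])
        try:
            res = pearson_chi_square(table.counts[[i, j]], comparison=comp)
            res.p_adjusted = _bonferroni(res.p, m)
        except StatsError as exc:
            res = StatResult(
                test="pearson_chi_square",
                statistic=float("nan"),
                df=float("nan"),
                p=float("nan"),
                p_adjusted=float("nan"),
                comparison=comp,
                note=f"failed: {exc}",
            )
        results.append(res)
    return results


def kruskal_wallis(
    groups: dict[str, np.ndarray], comparison: tuple = ()
) -> StatResult:
    """Kruskal-Wallis H test (midrank ties, chi-square approximation)."""
    names = [g for g in groups if np.isfinite(groups[g]).sum() > 0]
    dropped = [g for g in groups if g not in names]
    if len(names) < 2:
        raise StatsError("Kruskal-Wallis needs >= 2 non-empty groups")
    values = [np.asarray(groups[g], dtype=float) for g in names]
    values = [v[np.isfinite(v)] for v in values]
    H, p = sps.kruskal(*values)
    return StatResult(
        test="kruskal_wallis",
        statistic=float(H),
        df=float(len(names) - 1),
        p=float(p),
        p_adjusted=float(p),
        comparison=comparison,
        note=f"dropped: {','.join(dropped)}" if dropped else "",
    )


def dunn_posthoc(
    groups: dict[str, np.ndarray], family_size: int | None = None
) -> list[StatResult]:
    """Dunn's pairwise z-tests on pooled ranks with tie correction,
    Bonferroni-adjusted over the pair family."""
    names = [g for g in groups if np.isfinite(np.asarray(groups[g], float)).sum() > 0]
    values = {g: np.asarray(groups[g], float) for g in names}
    values = {g: v[np.isfinite(v)] for g, v in values.items()}
    pooled = np.concatenate([values[g] for g in names])
    ranks = sps.rankdata(pooled)
    N = len(pooled)
    # tie correction term
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (N - 1))
    var_factor = N * (N + 1) / 12.0 - tie_term
    mean_ranks = {}
    start = 0
    for g in names:
        n_g = len(values[g])
        mean_ranks[g] = ranks[start : start + n_g].mean()
        start += n_g
    pairs = list(itertools.combinations(names, 2))
    m = family_size if family_size is not None else len(pairs)
    results = []
    for a, b in pairs:
        se = np.sqrt(var_factor * (1.0 / len(values[a]) + 1.0 / len(values[b])))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        p = float(2.0 * sps.norm.sf(abs(z)))
        results.append(
            StatResult(
                test="dunn",
                statistic=float(z),
                df=float("nan"),
                p=p,
                p_adjusted=_bonferroni(p, m),
                comparison=(a, b),
            )
        )
    return results


def kruskal_wallis_by_dendrite(
    descriptor_values: dict[str, np.ndarray], comparison: tuple = ()
) -> tuple[StatResult, list[StatResult]]:
    """Omnibus Kruskal-Wallis across dendrites plus Dunn's post hoc."""
    omnibus = kruskal_wallis(descriptor_values, comparison=comparison)
    posthoc = dunn_posthoc(descriptor_values)
    return omnibus, posthoc


@dataclass
class ShuffleSummary:
    n_shuffles: int
    alpha: float
    rejection_fraction: dict[str, float] = field(default_factory=dict)

    def empty(self) -> bool:
        return self.n_shuffles == 0


def shuffle_control(
    dataset: NeuronDataset,
    labels: dict[str, int],
    n_shuffles: int,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
    descriptors: pd.DataFrame | None = None,
) -> ShuffleSummary:
    """Re-run the test battery on spine-to-dendrite shuffles.

    Each shuffle permutes the spine -> dendrite assignment while keeping
    the number of spines on every dendrite fixed, then recomputes the
    omnibus chi-square on the class table (and, when ``descriptors`` is
    given, the Kruskal-Wallis test per descriptor).  Reports the fraction
    of raw p < alpha per test family — the expected type-I rate under the
    null of exchangeable spines.
    """
    if n_shuffles == 0:
        return ShuffleSummary(n_shuffles=0, alpha=alpha)
    if rng is None:
        raise StatsError("shuffling requires a seeded rng")

    spine_ids: list[str] = []
    dendrite_of: list[str] = []
    for _, dendrite_id, ann in dataset.iter_spines():
        if ann.complete:
            spine_ids.append(ann.spine_id)
            dendrite_of.append(dendrite_id)
    dendrite_of = np.array(dendrite_of)
    class_of = np.array([labels[sid] for sid in spine_ids])
    class_ids = sorted(set(labels.values()))
    dendrites = list(dict.fromkeys(dendrite_of.tolist()))
    d_index = np.array([dendrites.index(d) for d in dendrite_of])
    c_index = np.array([class_ids.index(c) for c in class_of])

    desc_cols: list[str] = []
    desc_values = None
    if descriptors is not None:
        desc = descriptors.copy()
        if "spine_id" in desc.columns:
            desc = desc.set_index("spine_id")
        desc = desc.loc[spine_ids]
        desc_cols = [c for c in desc.columns if desc[c].dtype.kind == "f"]
        desc_values = {c: desc[c].to_numpy() for c in desc_cols}

    rejected = {"chi_square": 0}
    for c in desc_cols:
        rejected[f"kruskal_wallis:{c}"] = 0
    for _ in range(n_shuffles):
        perm = rng.permutation(len(spine_ids))
        # reassign spines to dendrite slots: per-dendrite counts preserved
        counts = np.zeros((len(dendrites), len(class_ids)), dtype=int)
        np.add.at(counts, (d_index, c_index[perm]), 1)
        try:
            res = pearson_chi_square(counts)
            if res.p < alpha:
                rejected["chi_square"] += 1
        except StatsError:
            pass
        if desc_values is not None:
            for c, vals in desc_values.items():
                shuffled = vals[perm]
                groups = {
                    d: shuffled[d_index == i] for i, d in enumerate(dendrites)
                }
                try:
                    res = kruskal_wallis(groups)
                    if res.p < alpha:
                        rejected[f"kruskal_wallis:{c}"] += 1
                except StatsError:
                    pass

    return ShuffleSummary(
        n_shuffles=n_shuffles,
        alpha=alpha,
        rejection_fraction={k: v / n_shuffles for k, v in rejected.items()},
    )
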