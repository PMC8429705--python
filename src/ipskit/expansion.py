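"""Cross-species Pfam-domain gene-family expansion testing.

The procedure: count each domain once per protein per species; for a focal
species, compare its per-domain count against a leave-one-out background
(the average of the remaining species) with a Fisher exact test on a 2x2
table whose margins are gene totals — the gene totals ARE the
normalisation; correct the p-values with Benjamini-Hochberg FDR; call a
domain expanded when q < alpha AND the focal proportion exceeds the
background proportion. Heatmap matrices report each domain row as z-scores
(standard deviations from the cross-species mean).

The two-sided Fisher p is computed in-package in log space from the
hypergeometric pmf (lgamma-based), exact to double precision for margins up
to real proteome scale (~1e5 genes); scipy's implementation is reserved for
independent cross-checks in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .exceptions import DataError, InputError
from ._util import round_half_away

# R's fisher.test two-sided rule: sum pmf values <= observed * (1 + eps)
_TWO_SIDED_REL_EPS = 1e-7


# ---------------------------------------------------------------------------
# inputs
# ---------------------------------------------------------------------------


def read_annotations_tsv(path: str | Path) -> pd.DataFrame:
    """Read a 3-column annotation TSV: species, protein_id, domain_accession."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = ["species", "protein_id", "domain_accession"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputError(f"annotation TSV missing columns: {missing}")
    return df[required]


def read_hmmscan_tblout(path: str | Path, species: str) -> pd.DataFrame:
    """Read hmmscan ``--tblout`` output into the annotation-table layout.

    Whitespace-delimited with '#' comment lines; column 1 is the domain
    (target) name, column 2 its accession, column 3 the query protein.
    The accession is used when present, the target name otherwise.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise InputError(f"malformed hmmscan tblout line: {line!r}")
            target, accession, query = fields[0], fields[1], fields[2]
            domain = accession if accession != "-" else target
            domain = domain.split(".")[0]  # strip Pfam accession version
            rows.append(
                {"species": species, "protein_id": query, "domain_accession": domain}
            )
    return pd.DataFrame(rows, columns=["species", "protein_id", "domain_accession"])


@dataclass
class DomainCountMatrix:
    """Per-species gene totals plus species x domain counts.

    A protein contributes at most once per domain, so every count is
    bounded by its species' gene total.
    """

    counts: pd.DataFrame  # species rows x domain columns, int
    gene_totals: pd.Series  # per species

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(int)
        self.gene_totals = self.gene_totals.astype(int).reindex(self.counts.index)
        if self.gene_totals.isna().any():
            missing = self.counts.index[self.gene_totals.isna()].tolist()
            raise InputError(f"gene totals missing for species: {missing}")
        if (self.gene_totals <= 0).any():
            raise InputError("gene totals must be positive")
        if (self.counts.to_numpy() < 0).any():
            raise InputError("domain counts must be non-negative")
        over = self.counts.gt(self.gene_totals, axis=0)
        if over.to_numpy().any():
            sp = self.counts.index[over.any(axis=1)].tolist()
            raise DataError(
                f"domain count exceeds gene total for species {sp}: a protein "
                "counts once per domain, so counts are bounded by gene totals"
            )

    @property
    def species(self) -> list[str]:
        return list(self.counts.index)

    @property
    def domains(self) -> list[str]:
        return list(self.counts.columns)

    def to_tsv(self, path: str | Path) -> None:
        out = self.counts.copy()
        out.insert(0, "gene_total", self.gene_totals)
        out.to_csv(path, sep="\t", index_label="species")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DomainCountMatrix":
        df = pd.read_csv(path, sep="\t", index_col="species", comment="#")
        if "gene_total" not in df.columns:
            raise InputError(
                "count-matrix TSV must have a gene_total column after species"
            )
        totals = df["gene_total"]
        return cls(counts=df.drop(columns="gene_total"), gene_totals=totals)


def build_count_matrix(
    annotations: pd.DataFrame, gene_totals: dict[str, int] | pd.Series
) -> DomainCountMatrix:
    """Collate once-per-protein domain counts per species.

    ``count(species, domain)`` = number of distinct proteins of that species
    containing the domain at least once; repeated hits of a domain within
    one protein collapse to one. Idempotent under duplicated annotation rows.
    """
    gene_totals = pd.Series(gene_totals, dtype=int)
    ann = annotations[["species", "protein_id", "domain_accession"]].drop_duplicates()
    missing = sorted(set(ann["species"]) - set(gene_totals.index))
    if missing:
        raise InputError(f"species present in annotations but not in gene_totals: {missing}")
    counts = (
        ann.groupby(["species", "domain_accession"])["protein_id"]
        .nunique()
        .unstack(fill_value=0)
    )
    counts = counts.reindex(index=gene_totals.index, fill_value=0)
    counts.columns.name = None
    counts.index.name = "species"
    return DomainCountMatrix(counts=counts, gene_totals=gene_totals)


# ---------------------------------------------------------------------------
# Fisher exact test (log-space, in-package)
# ---------------------------------------------------------------------------


def _log_hypergeom_pmf(x: np.ndarray, r1: int, r2: int, c1: int) -> np.ndarray:
    """log pmf of the table [[x, r1-x], [c1-x, r2-(c1-x)]] given both margins."""
    from scipy.special import gammaln

    n = r1 + r2

    def lchoose(nn, kk):
        return gammaln(nn + 1) - gammaln(kk + 1) - gammaln(nn - kk + 1)

    return lchoose(r1, x) + lchoose(r2, c1 - x) - lchoose(n, c1)


def fisher_exact_two_sided(
    a: int, b: int, c: int, d: int, alternative: str = "two-sided"
) -> float:
    """Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Conditions on both margins. ``two-sided`` sums hypergeometric
    probabilities not exceeding the observed one (with the customary 1+1e-7
    relative slack for floating-point ties); ``greater`` sums the upper
    tail of the first cell. Computed from cumulative log-factorials, so it
    stays exact-to-double for margins up to ~1e5.
    """
    if min(a, b, c, d) < 0:
        raise InputError("2x2 table entries must be non-negative")
    if alternative not in ("two-sided", "greater"):
        raise InputError("alternative must be 'two-sided' or 'greater'")
    r1, c1 = a + b, a + c
    n = a + b + c + d
    if n == 0 or r1 == 0 or r1 == n or c1 == 0 or c1 == n:
        return 1.0  # an empty margin admits a single table
    r2 = c + d
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    logp = _log_hypergeom_pmf(support, r1, r2, c1)
    if alternative == "greater":
        p = float(np.exp(logp[support >= a]).sum())
    else:
        logp_obs = float(logp[a - lo])
        p = float(
            np.exp(logp[logp <= logp_obs + math.log1p(_TWO_SIDED_REL_EPS)]).sum()
        )
    return min(1.0, p)


def _sample_odds_ratio(a: int, b: int, c: int, d: int) -> float:
    num, den = a * d, b * c
    if num == 0 and den == 0:
        return 1.0
    if den == 0:
        return math.inf
    return num / den


def fisher_expansion_test(
    matrix: DomainCountMatrix,
    focal_species: str,
    background: str = "rounded_mean",
    domains: Optional[Sequence[str]] = None,
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """Per-domain Fisher exact test of the focal species against the background.

    The background is the leave-one-out average over the remaining species.
    With ``background="rounded_mean"`` (default) the 2x2 table is::

        [[c_f, G_f - c_f], [round(mean_bg_count), round(mean_bg_genes) - round(mean_bg_count)]]

    where ``G_f`` is the focal gene total; ``background="pooled"`` instead
    sums counts and gene totals over the non-focal species. Direction
    compares the unrounded proportions ``c_f/G_f`` vs
    ``mean_bg_count/mean_bg_genes``.

    Returns a DataFrame indexed by domain with columns ``focal_count,
    bg_mean, odds_ratio, p_value, direction``.
    """
    if focal_species not in matrix.species:
        raise InputError(f"focal species {focal_species!r} not in matrix")
    if len(matrix.species) < 2:
        raise InputError("need at least 2 species")
    if background not in ("rounded_mean", "pooled"):
        raise InputError("background must be 'rounded_mean' or 'pooled'")

    sub = matrix.counts if domains is None else matrix.counts[list(domains)]
    focal = sub.loc[focal_species]
    bg_counts = sub.drop(index=focal_species)
    bg_totals = matrix.gene_totals.drop(index=focal_species)
    G_f = int(matrix.gene_totals[focal_species])

    bg_mean = bg_counts.mean(axis=0)
    bg_genes_mean = float(bg_totals.mean())

    if background == "rounded_mean":
        bg_c = bg_mean.map(round_half_away)
        bg_g = round_half_away(bg_genes_mean)
    else:
        bg_c = bg_counts.sum(axis=0)
        bg_g = int(bg_totals.sum())

    rows = []
    for dom in sub.columns:
        a = int(focal[dom])
        c = int(bg_c[dom])
        b, d = G_f - a, bg_g - c
        p = fisher_exact_two_sided(a, b, c, d, alternative=alternative)
        orat = _sample_odds_ratio(a, b, c, d)
        f_prop = a / G_f
        b_prop = bg_mean[dom] / bg_genes_mean
        if math.isclose(f_prop, b_prop, rel_tol=0, abs_tol=1e-15):
            direction = "none"
        elif f_prop > b_prop:
            direction = "up"
        else:
            direction = "down"
        rows.append(
            {
                "domain": dom,
                "focal_count": a,
                "bg_mean": float(bg_mean[dom]),
                "odds_ratio": orat,
                "p_value": p,
                "direction": direction,
            }
        )
    return pd.DataFrame(rows).set_index("domain")


def bh_fdr(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_expansions(test_results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Apply BH-FDR and the q < alpha AND direction == up expansion rule.

    Returns the input frame with ``q_value`` and ``expanded`` columns,
    sorted by q then descending odds ratio.
    """
    if not 0 < alpha < 1:
        raise InputError("alpha must lie in (0, 1)")
    out = test_results.copy()
    out["q_value"] = bh_fdr(out["p_value"].to_numpy())
    out["expanded"] = (out["q_value"] < alpha) & (out["direction"] == "up")
    return out.sort_values(
        ["q_value", "odds_ratio"], ascending=[True, False], kind="mergesort"
    )


def domain_zscores(
    matrix: DomainCountMatrix | pd.DataFrame, domains: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Domain x species z-score matrix for heatmap display.

    Each domain row is centred on its cross-species mean and scaled by its
    sample SD (n-1): cell values are "standard deviations from the mean".
    Constant rows map to all-zero.
    """
    counts = matrix.counts if isinstance(matrix, DomainCountMatrix) else matrix
    sub = counts if domains is None else counts[list(domains)]
    mat = sub.T.astype(float)  # domain rows x species columns
    mu = mat.mean(axis=1)
    sd = mat.std(axis=1, ddof=1)
    z = mat.sub(mu, axis=0).div(sd.replace(0.0, np.nan), axis=0).fillna(0.0)
    return z


# ---------------------------------------------------------------------------
# model/results facade
# ---------------------------------------------------------------------------


class DomainExpansionTest:
    """Gene-family expansion test for one focal species against the rest.

    Parameters
    ----------
    matrix : DomainCountMatrix
        Species x domain once-per-protein counts with gene totals.
    focal_species : str
        The species tested for expansions.
    background : {"rounded_mean", "pooled"}
        Leave-one-out background construction (see
        :func:`fisher_expansion_test`).
    family : {"nonzero", "focal_nonzero", "all"}
        The multiple-testing family: domains with a nonzero count in at
        least one species (default), domains present in the focal species,
        or every column of the matrix.
    """

    def __init__(
        self,
        matrix: DomainCountMatrix,
        focal_species: str,
        background: str = "rounded_mean",
        family: str = "nonzero",
        alternative: str = "two-sided",
    ):
        if family not in ("nonzero", "focal_nonzero", "all"):
            raise InputError("family must be 'nonzero', 'focal_nonzero' or 'all'")
        self.matrix = matrix
        self.focal_species = focal_species
        self.background = background
        self.family = family
        self.alternative = alternative

    def _family_domains(self) -> list[str]:
        c = self.matrix.counts
        if self.family == "nonzero":
            return list(c.columns[(c.sum(axis=0) > 0)])
        if self.family == "focal_nonzero":
            return list(c.columns[c.loc[self.focal_species] > 0])
        return list(c.columns)

    def fit(self, alpha: float = 0.05) -> "ExpansionResults":
        domains = self._family_domains()
        tests = fisher_expansion_test(
            self.matrix, self.focal_species, background=self.background,
            domains=domains, alternative=self.alternative,
        )
        calls = call_expansions(tests, alpha=alpha)
        return ExpansionResults(self, calls, alpha)


class ExpansionResults:
    """Fitted expansion-test results: per-domain statistics and calls."""

    def __init__(self, model: DomainExpansionTest, frame: pd.DataFrame, alpha: float):
        self.model = model
        self.frame = frame
        self.alpha = alpha

    @property
    def expanded_domains(self) -> list[str]:
        return list(self.frame.index[self.frame["expanded"]])

    @property
    def n_expanded(self) -> int:
        return int(self.frame["expanded"].sum())

    def zscores(self, domains: Optional[Iterable[str]] = None) -> pd.DataFrame:
        """Z-score heatmap matrix, defaulting to the expanded domains."""
        doms = list(domains) if domains is not None else self.expanded_domains
        return domain_zscores(self.model.matrix, doms)

    def to_tsv(self, path: str | Path) -> None:
        out = self.frame.copy()
        out.to_csv(path, sep="\t", index_label="domain", float_format="%.6g")

    def summary(self, max_rows: int = 25) -> str:
        head = self.frame.head(max_rows)
        lines = [
            "Domain expansion test",
            f"  focal species: {self.model.focal_species}",
            f"  background:    leave-one-out {self.model.background} "
            f"of {len(self.model.matrix.species) - 1} species",
            f"  family size:   {len(self.frame)} domains ({self.model.family})",
            f"  alpha:         {self.alpha} (BH-FDR corrected)",
            f"  expanded:      {self.n_expanded} domains",
            "",
            head.to_string(float_format=lambda v: f"{v:.3g}"),
        ]
        return "\n".join(lines)
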