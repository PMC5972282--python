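"""Phenotypic correlation analysis across traits, populations and
environments, with descriptive statistics per trait."""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import ENVIRONMENTS, TRAITS, AccessionMeta, PhenotypeTable

POPULATIONS = ("full", "indica", "japonica")


@dataclass
class CorrelationReport:
    """Pairwise Pearson correlations and per-trait descriptive stats."""

    correlations: pd.DataFrame  # population, environment, trait_a, trait_b, r, p, n
    descriptives: pd.DataFrame  # population, environment, trait, mean, sd, cv, n

    def get(
        self, population: str, environment: str, trait_a: str, trait_b: str
    ) -> tuple[float, float, int]:
        """(r, p, n) for one cell; trait order does not matter."""
        ta, tb = sorted((trait_a, trait_b))
        sel = self.correlations[
            (self.correlations["population"] == population)
            & (self.correlations["environment"] == environment)
            & (self.correlations["trait_a"] == ta)
            & (self.correlations["trait_b"] == tb)
        ]
        if sel.empty:
            raise KeyError(
                f"no cell ({population}, {environment}, {ta}, {tb})"
            )
        row = sel.iloc[0]
        return float(row["r"]), float(row["p"]), int(row["n"])


def correlate_traits(
    pheno: PhenotypeTable,
    meta: AccessionMeta,
    populations: tuple[str, ...] = POPULATIONS,
    environments: tuple[str, ...] = ENVIRONMENTS,
) -> CorrelationReport:
    """Pairwise-complete Pearson correlations per population x
    environment x trait pair, with two-tailed t-test p-values.

    Cells with fewer than three complete pairs are reported with NaN r
    and p.  Descriptives (mean, SD, coefficient of variation) use all
    non-missing values per cell.
    """
    corr_rows, desc_rows = [], []
    for population in populations:
        accs = meta.accessions_in(population)
        for env in environments:
            vectors = {
                t: pheno.vector(t, env, accs).to_numpy() for t in TRAITS
            }
            for t, v in vectors.items():
                vv = v[~np.isnan(v)]
                mean = float(vv.mean()) if vv.size else float("nan")
                sd = float(vv.std(ddof=1)) if vv.size > 1 else float("nan")
                desc_rows.append(
                    {
                        "population": population,
                        "environment": env,
                        "trait": t,
                        "mean": mean,
                        "sd": sd,
                        "cv": sd / mean if vv.size > 1 and mean != 0 else float("nan"),
                        "n": int(vv.size),
                    }
                )
            for ta, tb in itertools.combinations(sorted(TRAITS), 2):
                va, vb = vectors[ta], vectors[tb]
                ok = ~(np.isnan(va) | np.isnan(vb))
                n = int(ok.sum())
                if n < 3 or va[ok].std() == 0 or vb[ok].std() == 0:
                    r, p = float("nan"), float("nan")
                else:
                    r, p = stats.pearsonr(va[ok], vb[ok])
                corr_rows.append(
                    {
                        "population": population,
                        "environment": env,
                        "trait_a": ta,
                        "trait_b": tb,
                        "r": float(r),
                        "p": float(p),
                        "n": n,
                    }
                )
    return CorrelationReport(
        correlations=pd.DataFrame(corr_rows),
        descriptives=pd.DataFrame(desc_rows),
    )


def significance_summary(report: CorrelationReport, alpha: float = 0.05) -> str:
    """Plain-text matrix-style summary with significance stars."""
    lines = []
    for (population, env), grp in report.correlations.groupby(
        ["population", "environment"]
    ):
        lines.append(f"[{population} / {env}]")
        for _, row in grp.iterrows():
            star = ""
            if np.isfinite(row["p"]):
                if row["p"] < 0.01:
                    star = "**"
                elif row["p"] < alpha:
                    star = "*"
            r_txt = "NA" if not np.isfinite(row["r"]) else f"{row['r']:+.3f}"
            lines.append(
                f"  {row['trait_a']:>4s} vs {row['trait_b']:>4s}: "
                f"r={r_txt}{star} (n={int(row['n'])})"
            )
    return "\n".join(lines) + "\n"
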