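"""Packaged genetic-correlation / SNP-heritability reference matrix.

An 11-trait LDSC genetic correlation matrix over executive-function GWAS
(five UK Biobank cognitive tests, two CHARGE tests, the ALSPAC working
memory component, a stop-signal meta-analysis, and two NIHR BioResource
principal components), with SNP heritabilities on the diagonal and
jackknife standard errors throughout.  Shipped as a plain CSV
transcription and used as a desk-scale input for exercising the
covariance-structure machinery without any downloads.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class Table2Fixture:
    labels: tuple[str, ...]
    r_g: np.ndarray       # 11x11 genetic correlations, unit diagonal
    se: np.ndarray        # matching SEs (diagonal: SE of h2)
    h2: np.ndarray        # SNP heritabilities

    def submatrix(self, labels) -> "Table2Fixture":
        idx = [self.labels.index(l) for l in labels]
        return Table2Fixture(tuple(labels), self.r_g[np.ix_(idx, idx)],
                             self.se[np.ix_(idx, idx)], self.h2[idx])

    def covariance(self) -> np.ndarray:
        """Genetic covariance matrix S implied by r_g and h2."""
        sd = np.sqrt(self.h2)
        S = self.r_g * np.outer(sd, sd)
        S[np.diag_indices_from(S)] = self.h2
        return S


def table2_stack(labels=None):
    """Correlation-scale covariance stack from the packaged matrix.

    The sampling covariance is a diagonal surrogate built from the
    squared printed standard errors (the full off-diagonal sampling
    covariance of vech(S) is not published); unit diagonal entries carry
    the printed h2 standard errors.  Suitable for exercising model fits
    and rankings, not for reproducing published estimate-level results.
    """
    from .ldsc import CovarianceStack, vech_indices

    fx = table2_fixture()
    if labels is not None:
        fx = fx.submatrix(list(labels))
    R = fx.r_g.copy()
    dv = np.array([fx.se[i, j] ** 2 for i, j in vech_indices(len(fx.labels))])
    return CovarianceStack(list(fx.labels), R, np.diag(dv), 0)


def table2_fixture() -> Table2Fixture:
    """Load the packaged correlation matrix, symmetrically completed."""
    with resources.files("factorgwas.fixtures").joinpath("table2.csv").open() as fh:
        df = pd.read_csv(fh)
    labels: list[str] = []
    for t in df["trait_a"]:
        if t not in labels:
            labels.append(t)
    t = len(labels)
    r = np.eye(t)
    se = np.zeros((t, t))
    h2 = np.zeros(t)
    for row in df.itertuples():
        i, k = labels.index(row.trait_a), labels.index(row.trait_b)
        if i == k:
            h2[i] = row.value
            se[i, i] = row.se
        else:
            r[i, k] = r[k, i] = row.value
            se[i, k] = se[k, i] = row.se
    return Table2Fixture(tuple(labels), r, se, h2)
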