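"""Additive genotype coding and weighted multi-locus gene scores.

Genotypes at each scored locus are coded additively with respect to the
minor allele: 1 for major-allele homozygotes, 2 for heterozygotes, 3 for
minor-allele homozygotes.  The gene score of a subject is the weighted sum
of these codes across loci, with signed per-locus effect weights obtained
from a prior multiple regression of the phenotype on the codes.

Major/minor designations are taken from a supplied allele table rather than
recomputed from the sample, so coding is stable across subject subsets.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["code_genotypes", "compute_gene_score"]


def code_genotypes(raw_calls: pd.DataFrame, alleles: pd.DataFrame) -> pd.DataFrame:
    """Convert allele-pair call strings to additive genotype codes.

    Parameters
    ----------
    raw_calls : DataFrame, subjects x loci
        Each entry a two-character allele pair (e.g. ``"AG"``); order of the
        two alleles is irrelevant.  Missing calls may be NA or ``""``.
    alleles : DataFrame indexed by locus id with columns ``major``, ``minor``
        Designation of the major and minor allele per locus.

    Returns
    -------
    DataFrame of the same shape with integer codes 1/2/3 (float dtype so
    that missing calls can be carried as NaN until a missing-data policy is
    applied downstream).

    Raises
    ------
    ValueError
        If a call contains an allele not listed for its locus, naming the
        locus.
    """
    missing_loci = [c for c in raw_calls.columns if c not in alleles.index]
    if missing_loci:
        raise ValueError(f"no allele designation for loci: {missing_loci}")

    coded = pd.DataFrame(
        np.nan, index=raw_calls.index, columns=raw_calls.columns, dtype=float
    )
    for locus in raw_calls.columns:
        major = str(alleles.loc[locus, "major"])
        minor = str(alleles.loc[locus, "minor"])
        for subj, call in raw_calls[locus].items():
            if pd.isna(call) or call == "":
                continue
            call = str(call)
            if len(call) != 2:
                raise ValueError(f"malformed call {call!r} at locus {locus}")
            n_minor = 0
            for allele in call:
                if allele == minor:
                    n_minor += 1
                elif allele != major:
                    raise ValueError(
                        f"unknown allele {allele!r} at locus {locus} "
                        f"(major={major}, minor={minor})"
                    )
            coded.loc[subj, locus] = 1 + n_minor
    return coded


def compute_gene_score(
    genotypes: pd.DataFrame,
    weights: pd.Series,
    missing: str = "exclude",
) -> pd.Series:
    """Weighted sum of genotype codes across scored loci.

    ``score_i = sum_j weight_j * code_ij`` over the loci named in
    ``weights``.

    Parameters
    ----------
    genotypes : DataFrame, subjects x loci, codes in {1, 2, 3} (NaN = missing)
    weights : Series indexed by locus id, signed effect weights
    missing : {"exclude", "impute"}
        ``exclude`` drops subjects with any missing scored genotype (with a
        logged warning); ``impute`` fills each locus with its modal code.

    Returns
    -------
    Series of scores indexed by subject id (excluded subjects absent).
    """
    absent = [loc for loc in weights.index if loc not in genotypes.columns]
    if absent:
        raise ValueError(f"loci in weights missing from genotypes: {absent}")
    if not np.all(np.isfinite(weights.to_numpy(dtype=float))):
        raise ValueError("weights must be finite")

    codes = genotypes[list(weights.index)].astype(float)
    valid = codes.to_numpy()
    obs = valid[~np.isnan(valid)]
    if obs.size and not np.isin(obs, [1.0, 2.0, 3.0]).all():
        raise ValueError("genotype codes must be in {1, 2, 3}")

    if codes.isna().any().any():
        if missing == "exclude":
            bad = codes.index[codes.isna().any(axis=1)]
            warnings.warn(
                f"excluding {len(bad)} subject(s) with missing genotypes: "
                f"{list(bad)[:10]}",
                stacklevel=2,
            )
            codes = codes.drop(index=bad)
        elif missing == "impute":
            for locus in codes.columns:
                if codes[locus].isna().any():
                    mode = codes[locus].mode(dropna=True)
                    if mode.empty:
                        raise ValueError(f"locus {locus} entirely missing")
                    codes[locus] = codes[locus].fillna(mode.iloc[0])
        else:
            raise ValueError(f"unknown missing policy {missing!r}")

    score = codes @ weights.astype(float)
    score.name = "gene_score"
    return score
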