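"""Synthetic plex-structured proteomics + carotenoid data with known truth.

The study design being emulated: ~72 eight-channel multiplexed (iTRAQ)
experiments, each carrying 7 study samples and 1 pooled quality-control
channel; ~589 ± 65 proteins quantified per plex out of a catalogue of
several thousand; protein abundance expressed as log2 relative abundance,
median-referenced within each plex; plasma carotenoid concentrations with
lognormal marginals and left-censoring at an assay detection limit.

Carotenoid values are generated directly from the analysis model

    log2 C_rk = b0 + sum_j b1_j * P_jrk + B_r + e_rk

so that a downstream fit of the same model has a well-defined ground
truth (the TruthTable).  Missingness is plex-level: a protein undetected
in a plex is missing for every sample of that plex.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .abundance import AbundanceMatrix, CarotenoidTable
from .errors import InvalidDesignError, InvalidParameterError, UnknownProteinError


@dataclass
class PlexDesign:
    """Assignment of samples to multiplexed experiments.

    ``samples_per_plex`` counts analytic (study) samples; one pooled QC
    channel per plex is generated in addition and flagged via ``is_qc``.
    Plex indices are contiguous from 1.
    """

    n_plexes: int
    samples_per_plex: int
    sample_ids: list[str]
    plex_of: pd.Series          # sample_id -> plex index (1-based)
    is_qc: pd.Series            # sample_id -> bool

    def __post_init__(self) -> None:
        if set(self.plex_of.index) != set(self.sample_ids):
            raise InvalidDesignError("plex_of must cover exactly the sample ids")
        plexes = np.sort(self.plex_of.unique())
        if not np.array_equal(plexes, np.arange(1, len(plexes) + 1)):
            raise InvalidDesignError("plex indices must be contiguous from 1")
        analytic_per_plex = self.plex_of[~self.is_qc].value_counts()
        if (analytic_per_plex.reindex(plexes).fillna(0) < 1).any():
            raise InvalidDesignError("every plex needs >= 1 non-QC sample")

    @property
    def analytic_ids(self) -> list[str]:
        return [s for s in self.sample_ids if not self.is_qc[s]]

    @property
    def n_analytic(self) -> int:
        return int((~self.is_qc).sum())


@dataclass
class TruthTable:
    """Ground truth for one synthetic analyte.

    ``slopes`` maps protein id → true raw slope (log2 μmol/L per
    log2-unit abundance); unlisted proteins have slope 0.  ``b0_true`` is
    the overall mean log2 concentration, ``sigma_B``/``sigma_e`` the plex
    and residual SDs, and ``detection_limit`` the left-censoring point in
    μmol/L.
    """

    slopes: dict[str, float] = field(default_factory=dict)
    b0_true: float = 0.0
    sigma_B: float = 0.4
    sigma_e: float = 0.5
    detection_limit: float = 1e-6

    def __post_init__(self) -> None:
        if self.sigma_B < 0:
            raise InvalidParameterError("sigma_B must be >= 0")
        if self.sigma_e < 0:
            raise InvalidParameterError("sigma_e must be >= 0")
        if self.detection_limit <= 0:
            raise InvalidParameterError("detection_limit must be > 0")


def generate_design(
    n_plexes: int,
    samples_per_plex: int,
    seed: int,
    n_analytic: int | None = None,
) -> PlexDesign:
    """Lay out samples across plexes (deterministic under a fixed seed).

    ``n_analytic`` optionally subsamples the analytic slots (e.g. 500 of
    72 × 7 = 504) by dropping random slots while keeping at least one
    study sample per plex.
    """
    if n_plexes < 1 or samples_per_plex < 2:
        raise InvalidDesignError(
            "need n_plexes >= 1 and samples_per_plex >= 2"
        )
    rng = np.random.default_rng(seed)
    ids, plex, qc = [], [], []
    for r in range(1, n_plexes + 1):
        for j in range(1, samples_per_plex + 1):
            ids.append(f"plex{r:03d}_s{j}")
            plex.append(r)
            qc.append(False)
        ids.append(f"plex{r:03d}_qc")
        plex.append(r)
        qc.append(True)
    plex_of = pd.Series(plex, index=ids, name="plex")
    is_qc = pd.Series(qc, index=ids, name="is_qc")

    if n_analytic is not None:
        total = n_plexes * samples_per_plex
        if not (n_plexes <= n_analytic <= total):
            raise InvalidDesignError(
                f"n_analytic must lie in [{n_plexes}, {total}]"
            )
        analytic = [s for s, q in zip(ids, qc) if not q]
        drop_order = rng.permutation(len(analytic))
        remaining = {r: samples_per_plex for r in range(1, n_plexes + 1)}
        to_drop: set[str] = set()
        need = total - n_analytic
        for idx in drop_order:
            if need == 0:
                break
            sid = analytic[idx]
            r = int(plex_of[sid])
            if remaining[r] > 1:
                to_drop.add(sid)
                remaining[r] -= 1
                need -= 1
        ids = [s for s in ids if s not in to_drop]
        plex_of = plex_of.loc[ids]
        is_qc = is_qc.loc[ids]

    return PlexDesign(
        n_plexes=n_plexes,
        samples_per_plex=samples_per_plex,
        sample_ids=ids,
        plex_of=plex_of,
        is_qc=is_qc,
    )


def _protein_ids(n_catalogue: int) -> list[str]:
    width = max(4, len(str(n_catalogue)))
    return [f"P{i:0{width}d}" for i in range(1, n_catalogue + 1)]


def generate_proteome(
    design: PlexDesign,
    n_catalogue: int,
    mean_detected_per_plex: float,
    sd_detected_per_plex: float,
    abundance_sd: float,
    seed: int,
    prevalence_sd: float = 2.0,
) -> AbundanceMatrix:
    """Plex-structured log2 relative abundance matrix.

    Per-plex detected-protein counts are drawn as a rounded
    Normal(mean, sd) truncated to [1, n_catalogue].  Which proteins a
    plex detects is drawn with heavy-tailed per-protein prevalence
    weights (lognormal with SD ``prevalence_sd`` on the log scale), so
    the catalogue has a ubiquitous core and a long tail of rarely seen
    proteins, as in depleted-plasma multiplexed proteomics.  Detected
    values are Normal(0, abundance_sd) on the log2 scale, then centered
    so the within-plex per-protein median over study samples is exactly
    0.  Missingness is plex-level by construction.
    """
    if n_catalogue < 0:
        raise InvalidParameterError("n_catalogue must be >= 0")
    if abundance_sd <= 0:
        raise InvalidParameterError("abundance_sd must be > 0")
    rng = np.random.default_rng(seed)
    ids = list(design.sample_ids)
    proteins = _protein_ids(n_catalogue)
    meta = pd.DataFrame(
        {
            "gene_name": [f"Synthetic protein {i + 1}" for i in range(n_catalogue)],
            "gene_symbol": [f"G{i + 1:04d}" for i in range(n_catalogue)],
            "accession": [str(100000 + i + 1) for i in range(n_catalogue)],
        },
        index=pd.Index(proteins, name="protein_id"),
    )
    values = pd.DataFrame(
        np.nan, index=pd.Index(ids, name="sample_id"), columns=proteins
    )
    if n_catalogue == 0:
        return AbundanceMatrix(values=values, plex_of=design.plex_of.copy(),
                               is_qc=design.is_qc.copy(), protein_meta=meta)
    if not (1 <= mean_detected_per_plex <= n_catalogue):
        raise InvalidParameterError(
            "mean_detected_per_plex must lie in [1, n_catalogue]"
        )
    if sd_detected_per_plex < 0:
        raise InvalidParameterError("sd_detected_per_plex must be >= 0")

    log_w = rng.normal(0.0, prevalence_sd, size=n_catalogue)
    counts = np.rint(
        rng.normal(mean_detected_per_plex, sd_detected_per_plex, size=design.n_plexes)
    ).astype(int)
    counts = np.clip(counts, 1, n_catalogue)

    arr = values.to_numpy()
    row_of = {s: i for i, s in enumerate(ids)}
    analytic_mask = ~design.is_qc.loc[ids].to_numpy()
    for r in range(1, design.n_plexes + 1):
        rows = [row_of[s] for s in ids if design.plex_of[s] == r]
        rows = np.asarray(rows)
        d = counts[r - 1]
        # Gumbel top-k trick == weighted sampling without replacement
        keys = log_w + rng.gumbel(size=n_catalogue)
        detected = np.argpartition(-keys, d - 1)[:d]
        block = rng.normal(0.0, abundance_sd, size=(rows.size, d))
        sub_analytic = analytic_mask[rows]
        med = np.median(block[sub_analytic], axis=0) if sub_analytic.any() else 0.0
        arr[np.ix_(rows, detected)] = block - med

    values.iloc[:, :] = arr
    return AbundanceMatrix(
        values=values,
        plex_of=design.plex_of.copy(),
        is_qc=design.is_qc.copy(),
        protein_meta=meta,
    )


def generate_carotenoids(
    abundance: AbundanceMatrix,
    truths: Mapping[str, TruthTable] | TruthTable,
    design: PlexDesign,
    seed: int,
    analyte_name: str = "analyte",
) -> CarotenoidTable:
    """Carotenoid concentrations generated from the analysis model.

    For each analyte, over analytic samples where every slope protein is
    detected: log2 C = b0 + sum_j b1_j P_j + B_r + e, with B_r drawn per
    plex and e per sample; concentration = 2**log2C; values below the
    analyte's detection limit are flagged (not dropped).  Samples missing
    any slope protein get NaN concentration (analyte not generated).
    """
    if isinstance(truths, TruthTable):
        truths = {analyte_name: truths}
    rng = np.random.default_rng(seed)
    analytic = design.analytic_ids
    vals = abundance.values.loc[analytic]
    plex = design.plex_of.loc[analytic].to_numpy()
    conc = pd.DataFrame(
        np.nan, index=pd.Index(analytic, name="sample_id"), columns=list(truths)
    )
    lod = pd.DataFrame(False, index=conc.index, columns=conc.columns)
    for analyte, truth in truths.items():
        missing = [p for p in truth.slopes if p not in vals.columns]
        if missing:
            raise UnknownProteinError(
                f"analyte {analyte!r}: proteins absent from matrix: {missing[:5]}"
            )
        prots = list(truth.slopes)
        B = rng.normal(0.0, truth.sigma_B, size=design.n_plexes)
        eps = rng.normal(0.0, truth.sigma_e, size=len(analytic))
        if prots:
            X = vals[prots].to_numpy()
            ok = ~np.isnan(X).any(axis=1)
            fixed = X @ np.array([truth.slopes[p] for p in prots])
        else:
            ok = np.ones(len(analytic), dtype=bool)
            fixed = np.zeros(len(analytic))
        log2c = truth.b0_true + fixed + B[plex - 1] + eps
        c = np.exp2(log2c)
        c[~ok] = np.nan
        conc[analyte] = c
        lod[analyte] = np.where(ok, c < truth.detection_limit, False)
    return CarotenoidTable(concentrations=conc, below_lod=lod)
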