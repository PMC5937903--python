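"""Containers and preprocessing for plex-structured plasma proteomics data.

The quantification unit is one multiplexed (iTRAQ-style) experiment — a
"plex" — in which several plasma samples are labeled isobarically and
measured together.  Protein abundance is relative: each protein's log2
reporter intensity is referenced to the within-plex median for that protein,
so a value of 0 means "at the plex median" and +1 means "twice the plex
median".  Carotenoid concentrations are absolute (μmol/L) with a per-assay
detection limit; samples below the limit carry a flag and are excluded from
the log2 response rather than imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataIntegrityError

#: Analytes measured in the study design this package emulates.
CAROTENOIDS = (
    "beta_carotene",
    "lutein_zeaxanthin",
    "beta_cryptoxanthin",
    "alpha_carotene",
    "lycopene",
)


@dataclass
class AbundanceMatrix:
    """Samples × proteins grid of log2 relative abundances.

    Parameters
    ----------
    values
        DataFrame indexed by sample id with one column per protein;
        NaN marks a protein not detected for that sample.  Because
        detection happens per plex, missingness is expected to be
        plex-level: a protein absent from a plex is NaN for every
        sample of that plex.
    plex_of
        Series mapping sample id → integer plex index (contiguous from 1).
    is_qc
        Boolean Series over the same index; True marks the pooled
        quality-control channel, which is carried through normalization
        but excluded from every analytic computation.
    protein_meta
        Optional DataFrame indexed by protein id with columns
        ``gene_name``, ``gene_symbol`` and ``accession``.
    """

    values: pd.DataFrame
    plex_of: pd.Series
    is_qc: pd.Series | None = None
    protein_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.is_qc is None:
            self.is_qc = pd.Series(False, index=self.values.index)
        missing = self.values.index.difference(self.plex_of.index)
        if len(missing):
            raise DataIntegrityError(
                f"samples without a plex assignment: {list(missing)[:5]}"
            )
        self.plex_of = self.plex_of.reindex(self.values.index).astype(int)
        self.is_qc = self.is_qc.reindex(self.values.index).fillna(False).astype(bool)

    # -- convenience views -------------------------------------------------
    @property
    def analytic_index(self) -> pd.Index:
        """Sample ids of study (non-QC) samples."""
        return self.values.index[~self.is_qc.values]

    @property
    def analytic_values(self) -> pd.DataFrame:
        return self.values.loc[self.analytic_index]

    @property
    def proteins(self) -> pd.Index:
        return self.values.columns

    def detection_n(self) -> pd.Series:
        """Per-protein count of non-missing analytic samples."""
        return self.analytic_values.notna().sum(axis=0)

    def subset(self, proteins) -> "AbundanceMatrix":
        meta = None
        if self.protein_meta is not None:
            meta = self.protein_meta.reindex(proteins)
        return AbundanceMatrix(
            values=self.values.loc[:, proteins],
            plex_of=self.plex_of.copy(),
            is_qc=self.is_qc.copy(),
            protein_meta=meta,
        )


@dataclass
class CarotenoidTable:
    """Samples × analytes carotenoid concentrations (μmol/L) with
    below-detection flags.

    Concentrations below the detection limit are retained with
    ``below_lod`` set, so the exclusion policy lives in
    :func:`prepare_response` alone.  NaN concentration means the analyte
    was not measurable for that sample at all (e.g. the generating
    proteins were undetected in a synthetic run).
    """

    concentrations: pd.DataFrame
    below_lod: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.below_lod is None:
            self.below_lod = pd.DataFrame(
                False, index=self.concentrations.index, columns=self.concentrations.columns
            )
        if not self.below_lod.index.equals(self.concentrations.index) or not (
            self.below_lod.columns.equals(self.concentrations.columns)
        ):
            raise DataIntegrityError("below_lod flags not aligned with concentrations")
        bad = (
            (self.concentrations <= 0)
            & self.concentrations.notna()
            & ~self.below_lod
        )
        if bad.to_numpy().any():
            raise DataIntegrityError(
                "non-positive concentration not flagged below detection limit"
            )

    @property
    def analytes(self) -> pd.Index:
        return self.concentrations.columns

    def detectable_n(self) -> pd.Series:
        """Per-analyte count of samples with a detectable concentration."""
        return (self.concentrations.notna() & ~self.below_lod).sum(axis=0)


@dataclass
class Response:
    """Log2 concentration response for one analyte, after LOD exclusion."""

    analyte: str
    values: pd.Series            # log2 μmol/L, indexed by retained sample id
    excluded: list[tuple[str, str]]   # (sample_id, reason)

    def __len__(self) -> int:
        return len(self.values)


def median_center(m: AbundanceMatrix, include_qc: bool = False) -> AbundanceMatrix:
    """Reference each protein to its within-plex median.

    For every (protein, plex) cell the plex median of the protein's
    non-missing values is subtracted, so the per-protein within-plex median
    of the output is exactly 0 (midpoint convention for even counts).  The
    operation is idempotent.  By default the pooled QC channel does not
    contribute to the median (it is not a study sample); pass
    ``include_qc=True`` to median over all channels of the plex.
    """
    ref_index = m.values.index if include_qc else m.analytic_index
    med = m.values.loc[ref_index].groupby(m.plex_of.loc[ref_index]).median()
    # broadcast plex medians back to samples
    offset = med.reindex(m.plex_of.values)
    offset.index = m.values.index
    centered = m.values - offset
    return AbundanceMatrix(
        values=centered,
        plex_of=m.plex_of.copy(),
        is_qc=m.is_qc.copy(),
        protein_meta=None if m.protein_meta is None else m.protein_meta.copy(),
    )


def filter_detection(
    m: AbundanceMatrix,
    total_samples: int | None = None,
    min_fraction: float = 0.10,
) -> AbundanceMatrix:
    """Keep proteins detected in strictly more than ``min_fraction`` of samples.

    The inequality is strict (n > fraction·N, not ≥), so with N=500 and the
    default 10% threshold a protein needs at least 51 detections to survive.
    """
    if not (0 <= min_fraction < 1):
        raise ValueError("min_fraction must be in [0, 1)")
    if total_samples is None:
        total_samples = len(m.analytic_index)
    keep = m.detection_n() > min_fraction * total_samples
    return m.subset(m.proteins[keep.values])


def prepare_response(t: CarotenoidTable, analyte: str) -> Response:
    """Log2-transform one analyte's concentrations, excluding below-LOD samples.

    Returns the log2(μmol/L) response over samples with a detectable
    concentration, together with the list of excluded sample ids and the
    reason each was dropped (``below_lod`` or ``not_measured``).
    """
    if analyte not in t.analytes:
        raise KeyError(f"unknown analyte {analyte!r}")
    conc = t.concentrations[analyte]
    flag = t.below_lod[analyte]
    excluded: list[tuple[str, str]] = []
    keep = []
    for sid, c, f in zip(conc.index, conc.to_numpy(), flag.to_numpy()):
        if f:
            excluded.append((sid, "below_lod"))
        elif np.isnan(c):
            excluded.append((sid, "not_measured"))
        elif c <= 0:
            raise DataIntegrityError(
                f"sample {sid!r}: non-positive concentration {c} not flagged below LOD"
            )
        else:
            keep.append(sid)
    values = np.log2(conc.loc[keep].astype(float))
    values.name = analyte
    return Response(analyte=analyte, values=values, excluded=excluded)
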