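"""TSV dialects for the pipeline's on-disk objects.

All files are tab-separated text with a header row; the first column is
``sample_id`` (or ``protein_id`` / ``analyte``); an empty cell is missing.
Each file starts with a ``# seed=...`` comment line echoing the generating
seed, ignored by the readers.  Floats round-trip exactly (shortest-repr
formatting).
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd

from .abundance import AbundanceMatrix, CarotenoidTable
from .errors import ConfigError, DataIntegrityError
from .synthdata import PlexDesign, TruthTable

ABUNDANCE_TSV = "abundance.tsv"
PLEXMAP_TSV = "plexmap.tsv"
PROTEIN_META_TSV = "protein_meta.tsv"
CAROTENOID_TSV = "carotenoids.tsv"
CAROTENOID_LOD_TSV = "carotenoid_lod.tsv"
TRUTH_SLOPES_TSV = "truth_slopes.tsv"
TRUTH_PARAMS_TSV = "truth_params.tsv"


def _write_tsv(df: pd.DataFrame, path: Path, seed: int | None) -> None:
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        df.to_csv(fh, sep="\t")


def _read_tsv(path: Path, **kw) -> pd.DataFrame:
    if not Path(path).exists():
        raise ConfigError(f"required input file missing: {path}")
    try:
        return pd.read_csv(path, sep="\t", comment="#", **kw)
    except pd.errors.ParserError as exc:  # pandas names the offending line
        raise DataIntegrityError(f"malformed TSV {path}: {exc}") from exc


def write_abundance(m: AbundanceMatrix, outdir: str | Path, seed: int | None = None) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _write_tsv(m.values, outdir / ABUNDANCE_TSV, seed)
    plexmap = pd.DataFrame(
        {"plex": m.plex_of, "is_qc": m.is_qc.astype(int)},
    )
    plexmap.index.name = "sample_id"
    _write_tsv(plexmap, outdir / PLEXMAP_TSV, seed)
    if m.protein_meta is not None:
        _write_tsv(m.protein_meta, outdir / PROTEIN_META_TSV, seed)


def read_abundance(indir: str | Path) -> AbundanceMatrix:
    indir = Path(indir)
    values = _read_tsv(indir / ABUNDANCE_TSV, index_col=0)
    values.index.name = "sample_id"
    plexmap = _read_tsv(indir / PLEXMAP_TSV, index_col=0)
    meta_path = indir / PROTEIN_META_TSV
    meta = _read_tsv(meta_path, index_col=0, dtype=str) if meta_path.exists() else None
    return AbundanceMatrix(
        values=values,
        plex_of=plexmap["plex"].astype(int),
        is_qc=plexmap["is_qc"].astype(bool),
        protein_meta=meta,
    )


def write_carotenoids(t: CarotenoidTable, outdir: str | Path, seed: int | None = None) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _write_tsv(t.concentrations, outdir / CAROTENOID_TSV, seed)
    _write_tsv(t.below_lod.astype(int), outdir / CAROTENOID_LOD_TSV, seed)


def read_carotenoids(indir: str | Path) -> CarotenoidTable:
    indir = Path(indir)
    conc = _read_tsv(indir / CAROTENOID_TSV, index_col=0)
    lod = _read_tsv(indir / CAROTENOID_LOD_TSV, index_col=0).astype(bool)
    return CarotenoidTable(concentrations=conc, below_lod=lod)


def write_truths(truths: Mapping[str, TruthTable], outdir: str | Path,
                 seed: int | None = None) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = [
        {"analyte": a, "protein_id": p, "slope": s}
        for a, t in truths.items() for p, s in t.slopes.items()
    ]
    slopes = pd.DataFrame(rows, columns=["analyte", "protein_id", "slope"])
    _write_tsv(slopes.set_index("analyte"), outdir / TRUTH_SLOPES_TSV, seed)
    params = pd.DataFrame(
        {
            "analyte": list(truths),
            "b0_true": [t.b0_true for t in truths.values()],
            "sigma_B": [t.sigma_B for t in truths.values()],
            "sigma_e": [t.sigma_e for t in truths.values()],
            "detection_limit": [t.detection_limit for t in truths.values()],
        }
    ).set_index("analyte")
    _write_tsv(params, outdir / TRUTH_PARAMS_TSV, seed)


def read_truths(indir: str | Path) -> dict[str, TruthTable]:
    indir = Path(indir)
    params = _read_tsv(indir / TRUTH_PARAMS_TSV, index_col=0)
    slopes = _read_tsv(indir / TRUTH_SLOPES_TSV)
    out: dict[str, TruthTable] = {}
    for analyte, row in params.iterrows():
        sl = slopes[slopes["analyte"] == analyte]
        out[str(analyte)] = TruthTable(
            slopes=dict(zip(sl["protein_id"], sl["slope"].astype(float))),
            b0_true=float(row["b0_true"]),
            sigma_B=float(row["sigma_B"]),
            sigma_e=float(row["sigma_e"]),
            detection_limit=float(row["detection_limit"]),
        )
    return out


def design_from_abundance(m: AbundanceMatrix) -> PlexDesign:
    """Reconstruct the plex design implied by an abundance matrix."""
    plexes = m.plex_of.unique()
    per_plex = m.plex_of[~m.is_qc].value_counts()
    return PlexDesign(
        n_plexes=int(len(plexes)),
        samples_per_plex=int(per_plex.max()),
        sample_ids=list(m.values.index),
        plex_of=m.plex_of.copy(),
        is_qc=m.is_qc.copy(),
    )
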