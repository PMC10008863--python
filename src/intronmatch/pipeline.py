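"""End-to-end helpers shared by the command-line interface and tests."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .align import OptimalMatchedSegment, find_oms, get_scheme
from .genemodels import TranscriptModel, classify_intron
from .rfstats import RFProfile, rf_profile_from_oms

OMS_COLUMNS = [
    "mrna_id",
    "intron_id",
    "intron_index",
    "scheme",
    "orientation",
    "mrna_start",
    "mrna_end",
    "intron_start",
    "intron_end",
    "score",
    "identities",
    "columns",
    "gap_columns",
    "match_rate",
]


def align_models(
    models: Sequence[TranscriptModel],
    scheme_name: str = "BFE",
    orientation: str = "complement",
) -> list[OptimalMatchedSegment]:
    """One OMS per (mRNA, intron) pair, in model order."""
    scheme = get_scheme(scheme_name)
    out = []
    for m in models:
        for iid, _, iseq in m.iter_pairs():
            out.append(
                find_oms(
                    m.mrna_seq,
                    iseq,
                    scheme,
                    orientation=orientation,
                    mrna_id=m.transcript_id,
                    intron_id=iid,
                )
            )
    return out


def pair_lengths(models: Sequence[TranscriptModel]) -> list[int]:
    """mRNA length repeated once per intron, matching align_models order."""
    return [m.length for m in models for _ in m.introns]


def oms_table(
    models: Sequence[TranscriptModel], oms_list: Sequence[OptimalMatchedSegment]
) -> pd.DataFrame:
    idx_of = {
        iid: i for m in models for iid, i, _ in m.iter_pairs()
    }
    rows = []
    for o in oms_list:
        rows.append(
            (
                o.tested_id,
                o.aligned_id,
                idx_of.get(o.aligned_id, 0),
                o.scheme_name,
                o.orientation,
                o.tested_start,
                o.tested_end,
                o.intron_start,
                o.intron_end,
                o.score,
                o.n_identities,
                o.n_columns,
                o.n_gap_columns,
                round(o.match_rate, 4) if not o.is_empty else float("nan"),
            )
        )
    return pd.DataFrame(rows, columns=OMS_COLUMNS)


def rf_from_models(
    models: Sequence[TranscriptModel],
    oms_list: Sequence[OptimalMatchedSegment],
    intron_class: str = "all",
    long_short_threshold: int = 80,
) -> RFProfile:
    """Normalized 100-bin RF profile, optionally per intron-length class."""
    ilen = {iid: len(s) for m in models for iid, _, s in m.iter_pairs()}
    keep_oms, keep_len = [], []
    lengths = pair_lengths(models)
    for o, L in zip(oms_list, lengths):
        if intron_class != "all":
            if classify_intron(ilen[o.aligned_id], long_short_threshold) != intron_class:
                continue
        keep_oms.append(o)
        keep_len.append(L)
    scheme = oms_list[0].scheme_name if oms_list else ""
    orient = oms_list[0].orientation if oms_list else "complement"
    return rf_profile_from_oms(keep_oms, keep_len, scheme_name=scheme, orientation=orient)


def oms_by_pair(
    oms_list: Sequence[OptimalMatchedSegment],
) -> dict[tuple[str, str], OptimalMatchedSegment]:
    return {(o.tested_id, o.aligned_id): o for o in oms_list}


def write_tsv(df: pd.DataFrame, path: str | Path, meta: dict | None = None) -> None:
    """TSV with ``#``-prefixed header lines echoing the configuration."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# intronmatch {__version__}\n")
        for k, v in (meta or {}).items():
            fh.write(f"# {k} = {v}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
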