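"""Result serialization: candidate TSV, BED6 companion, run summary, config.

The TSV carries every filter input so a run is auditable from the file
alone.  Genomic coordinates are 0-based half-open in both TSV and BED.
"""

from __future__ import annotations

import hashlib
from typing import Iterable, List, Optional

import pandas as pd
import yaml

from .filters import FilterParams
from .scanner import IRRecord, frame_to_records, records_to_frame

#: config keys (paper-style threshold names) -> FilterParams fields
CONFIG_KEYS = {
    "d-min": "D_min",
    "d-max": "D_max",
    "p-max": "P_max",
    "a-min": "A_min",
    "g-min": "G_min",
    "min-len": "L_min",
}


def write_candidates_tsv(records: Iterable[IRRecord], path) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False)


def read_candidates_tsv(path) -> List[IRRecord]:
    frame = pd.read_csv(path, sep="\t", dtype={"contig": str, "pairing": str, "sequence": str})
    return frame_to_records(frame)


def write_bed(records: Iterable[IRRecord], path) -> None:
    """BED6 companion; score is the alignment score capped at 1000."""
    with open(path, "w") as fh:
        for r in records:
            name = f"{r.contig}:{r.start}-{r.end}/w{r.window_size}"
            fh.write(
                f"{r.contig}\t{r.start}\t{r.end}\t{name}\t{min(r.score, 1000)}\t+\n"
            )


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def params_to_dict(params: FilterParams) -> dict:
    return {key: getattr(params, attr) for key, attr in CONFIG_KEYS.items()}


def write_summary(path, **sections) -> None:
    """Plain-text (YAML) run summary; must suffice to reproduce the run."""
    with open(path, "w") as fh:
        yaml.safe_dump(sections, fh, default_flow_style=False, sort_keys=False)


def load_config(path) -> dict:
    """Flat key-value config mirroring the CLI flags."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a flat key-value mapping")
    unknown = set(data) - set(CONFIG_KEYS) - {"windows"}
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    return data


def params_from_config(
    config: dict, base: Optional[FilterParams] = None
) -> FilterParams:
    base = base or FilterParams.base()
    kw = {
        attr: config[key]
        for key, attr in CONFIG_KEYS.items()
        if key in config and config[key] is not None
    }
    return base.replace(**kw) if kw else base
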