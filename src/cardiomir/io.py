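"""Readers and writers for the flat-text formats the stages exchange.

Stages communicate exclusively through plain-text files (TSV, GMT, CSV,
GraphML, JSON, Newick) so each stage is independently testable.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from cardiomir.exceptions import InputError


def read_gmt(path) -> dict[str, set]:
    """GMT gene-set collection: name <tab> description <tab> genes..."""
    sets: dict[str, set] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise InputError(f"{path}:{line_no}: GMT rows need name, description, >=1 gene")
            sets[parts[0]] = set(parts[2:])
    return sets


def write_gmt(gene_sets: Mapping[str, Iterable], path, descriptions: Mapping[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for name in sorted(gene_sets):
            genes = sorted(gene_sets[name])
            desc = descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_gene_list(path) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def write_gene_list(genes: Iterable, path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(f"{g}\n")


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_json(payload, path) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def row_count(path) -> int:
    with open(path, "rb") as fh:
        return sum(1 for _ in fh)


def file_record(path) -> dict:
    path = Path(path)
    return {"path": path.name, "sha256": sha256_of(path), "rows": row_count(path)}
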