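"""Reading and writing the pipeline's plain-text formats.

Inputs: SMILES files (``SMILES<tab>id`` per line), pair CSVs
(``pair_id,smiles_a,smiles_b``), similarity CSVs (``pair_id`` plus one
column per scheme), and vote CSVs (``pair_id,yes_fraction``).  Output CSVs
carry a single ``#``-prefixed provenance line naming the seed and config
hash, which pandas skips on read.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import CalibrationModel, label_majority
from .fingerprints import MoleculeRecord, SimilarityProfile, parse_molecule


def read_smiles_file(path) -> list[MoleculeRecord]:
    """Read a ``SMILES<tab>id`` file (whitespace-separated; '#' comments allowed)."""
    records = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 2:
            raise ValueError(f"{path}:{lineno}: expected 'SMILES id', got {line!r}")
        records.append(parse_molecule(parts[0], parts[1]))
    return records


def read_pairs_csv(path) -> list[tuple[str, MoleculeRecord, MoleculeRecord]]:
    """Read a pairs CSV with columns pair_id, smiles_a, smiles_b."""
    df = pd.read_csv(path, comment="#", dtype=str)
    required = {"pair_id", "smiles_a", "smiles_b"}
    if not required.issubset(df.columns):
        raise ValueError(f"pairs CSV must have columns {sorted(required)}")
    out = []
    for row in df.itertuples(index=False):
        a = parse_molecule(row.smiles_a, f"{row.pair_id}_a")
        b = parse_molecule(row.smiles_b, f"{row.pair_id}_b")
        out.append((str(row.pair_id), a, b))
    return out


def read_votes_csv(path) -> dict[str, float]:
    df = pd.read_csv(path, comment="#")
    if not {"pair_id", "yes_fraction"}.issubset(df.columns):
        raise ValueError("votes CSV must have columns pair_id, yes_fraction")
    return {str(r.pair_id): float(r.yes_fraction) for r in df.itertuples(index=False)}


def attach_votes(profiles: list[SimilarityProfile], votes: dict[str, float]) -> None:
    """Attach yes-fractions (and the derived majority labels) in place."""
    for prof in profiles:
        if prof.pair_id not in votes:
            raise ValueError(f"no vote record for pair {prof.pair_id!r}")
        prof.yes_fraction = votes[prof.pair_id]
        prof.majority_label = label_majority(prof.yes_fraction)


def profiles_to_frame(profiles: list[SimilarityProfile]) -> pd.DataFrame:
    """Flatten profiles into a frame: pair_id, one column per scheme, votes/labels."""
    schemes = sorted({s for p in profiles for s in p.similarities})
    rows = []
    for p in profiles:
        row = {"pair_id": p.pair_id, "molecule_a_id": p.molecule_a_id,
               "molecule_b_id": p.molecule_b_id}
        row.update({s: p.similarities.get(s, np.nan) for s in schemes})
        if p.yes_fraction is not None:
            row["yes_fraction"] = p.yes_fraction
        if p.majority_label is not None:
            row["majority_label"] = int(p.majority_label)
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_profiles(df: pd.DataFrame, schemes: list[str]) -> list[SimilarityProfile]:
    profiles = []
    for d in df.to_dict("records"):  # itertuples would mangle hyphenated scheme names
        profiles.append(
            SimilarityProfile(
                pair_id=str(d["pair_id"]),
                molecule_a_id=str(d.get("molecule_a_id", "")),
                molecule_b_id=str(d.get("molecule_b_id", "")),
                similarities={s: float(d[s]) for s in schemes if s in d and pd.notna(d[s])},
                yes_fraction=float(d["yes_fraction"]) if "yes_fraction" in d and pd.notna(d.get("yes_fraction")) else None,
                majority_label=bool(int(d["majority_label"])) if "majority_label" in d and pd.notna(d.get("majority_label")) else None,
            )
        )
    return profiles


def read_similarity_csv(path, schemes: list[str]) -> list[SimilarityProfile]:
    return frame_to_profiles(pd.read_csv(path, comment="#"), schemes)


def format_frame(df: pd.DataFrame, precision: int = 3, mcc_precision: int = 4) -> pd.DataFrame:
    """Format float columns to fixed decimals (MCC columns one digit more)."""
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            digits = mcc_precision if "mcc" in str(col).lower() else precision
            out[col] = out[col].map(lambda v, d=digits: "" if pd.isna(v) else f"{v:.{d}f}")
    return out


def write_report_csv(df: pd.DataFrame, path, seed: int, config_hash: str,
                     precision: int = 3, index: bool = False) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    body = format_frame(df, precision=precision).to_csv(index=index)
    path.write_text(f"# seed={seed} config_sha={config_hash}\n" + body)


def read_report_csv(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", index_col=index_col)


def model_to_dict(model: CalibrationModel) -> dict:
    d = dataclasses.asdict(model)
    d["cov"] = None if model.cov is None else np.asarray(model.cov).tolist()
    return d


def write_model_json(model: CalibrationModel, path, seed: int, config_hash: str) -> None:
    payload = {"seed": seed, "config_sha": config_hash, "model": model_to_dict(model)}
    Path(path).write_text(json.dumps(payload, indent=2, allow_nan=True) + "\n")
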