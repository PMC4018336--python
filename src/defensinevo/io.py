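"""Readers, writers and report formatting.

FASTA goes through Biopython; coordinate files are standard fixed-column
ATOM records (single- or multi-MODEL), parsed with Bio.PDB and written by a
minimal fixed-column writer. TSV reports start with '#' comment headers
recording tool version, subcommand, parameters and seed; undefined
statistics print as 'NA'. All coordinates in files and reports are 1-based
inclusive. FASTA and coordinate outputs are kept header-free so downstream
tools parse them unmodified; their parameters travel in a JSON sidecar.
"""

from __future__ import annotations

import json
import math
import warnings
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.PDB import PDBParser

from . import __version__
from .geometry import DimerStructure
from .rates import WindowStat


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[tuple[str, str]]:
    """Read (id, sequence) records; order preserved, sequences uppercased,
    wrapped lines and CRLF accepted, gaps retained.

    Raises on an empty file or duplicate ids.
    """
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        records.append((rec.id, str(rec.seq).upper()))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Sequence[tuple[str, str]], path, wrap: int = 60) -> None:
    """Write records with fixed 60-column wrapping (round-trips byte-identically)."""
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), wrap):
                fh.write(seq[i : i + wrap] + "\n")


# ---------------------------------------------------------------------------
# Coordinate files (fixed-column ATOM records)
# ---------------------------------------------------------------------------

def read_coordinates(
    path,
    chain_order: Optional[tuple[str, str]] = None,
    numbering_map: Optional[dict] = None,
) -> list[DimerStructure]:
    """Parse a single- or multi-MODEL coordinate file into dimer frames.

    MODEL index becomes the frame index. The first two chains in file order
    map to roles A and B unless ``chain_order`` overrides them.
    """
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = parser.get_structure("traj", str(path))
    frames = []
    for k, model in enumerate(structure, start=1):
        chains: dict[str, dict[int, dict[str, np.ndarray]]] = {}
        order: list[str] = []
        for chain in model:
            cid = chain.id
            order.append(cid)
            residues: dict[int, dict[str, np.ndarray]] = {}
            for res in chain:
                resnum = res.id[1]
                residues[resnum] = {
                    atom.get_name(): np.asarray(atom.coord, dtype=float)
                    for atom in res
                }
            chains[cid] = residues
        if chain_order is None:
            if len(order) < 2:
                raise ValueError(
                    f"frame {k} of {path} has {len(order)} chain(s); a dimer needs two"
                )
            pair = (order[0], order[1])
        else:
            pair = chain_order
        frames.append(DimerStructure(chains, pair, numbering_map, frame=k))
    if not frames:
        raise ValueError(f"no MODEL/ATOM records in {path}")
    return frames


_ATOM_FMT = (
    "ATOM  {serial:>5d} {name:^4s}{altloc:1s}{resname:>3s} {chain:1s}"
    "{resnum:>4d}{icode:1s}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}"
    "          {element:>2s}\n"
)


def write_coordinates(frames: Sequence[DimerStructure], path) -> None:
    """Write frames as a multi-MODEL fixed-column coordinate file."""
    atom_order = ("N", "CA", "C", "O")
    with open(path, "w") as fh:
        multi = len(frames) > 1
        for frame in frames:
            if multi:
                fh.write(f"MODEL     {frame.frame:>4d}\n")
            serial = 1
            for cid in frame.chain_order:
                for resnum in sorted(frame.chains[cid]):
                    atoms = frame.chains[cid][resnum]
                    names = [n for n in atom_order if n in atoms]
                    names += [n for n in sorted(atoms) if n not in atom_order]
                    for name in names:
                        x, y, z = atoms[name]
                        fh.write(
                            _ATOM_FMT.format(
                                serial=serial,
                                name=name if len(name) >= 4 else f" {name}",
                                altloc=" ",
                                resname="GLY",
                                chain=cid,
                                resnum=resnum,
                                icode=" ",
                                x=x, y=y, z=z,
                                occ=1.0, b=0.0,
                                element=name[0],
                            )
                        )
                        serial += 1
                fh.write("TER\n")
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------

def read_config(path) -> dict:
    """Load a key-value (YAML) run-configuration file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a key-value mapping")
    return cfg


# ---------------------------------------------------------------------------
# TSV reports
# ---------------------------------------------------------------------------

def _header_lines(subcommand: str, params: dict) -> str:
    items = " ".join(f"{k}={v}" for k, v in params.items())
    return (
        f"# defensinevo {__version__}\n"
        f"# subcommand: {subcommand}\n"
        f"# parameters: {items}\n"
    )


def write_tsv(df: pd.DataFrame, path, subcommand: str, params: dict) -> None:
    """Write a report TSV with the standard comment header and 'NA' for
    undefined values."""
    with open(path, "w") as fh:
        fh.write(_header_lines(subcommand, params))
        df.to_csv(fh, sep="\t", index=False, na_rep="NA", float_format="%.6g")


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


WINDOW_COLUMNS = [
    "start", "end", "identity_pct", "avg_Ka", "avg_Ks", "avg_KaKs",
    "n_pairs_used", "direction", "boot_mean", "boot_sd", "p_value",
]


def window_stats_frame(stats: Iterable[WindowStat]) -> pd.DataFrame:
    rows = []
    for st in stats:
        rows.append(
            {
                "start": st.start,
                "end": st.end,
                "identity_pct": _na(st.identity),
                "avg_Ka": _na(st.avg_Ka),
                "avg_Ks": _na(st.avg_Ks),
                "avg_KaKs": _na(st.avg_KaKs),
                "n_pairs_used": st.n_pairs_used,
                "direction": st.direction or None,
                "boot_mean": _na(st.boot_mean),
                "boot_sd": _na(st.boot_sd),
                "p_value": _na(st.p_value),
            }
        )
    return pd.DataFrame(rows, columns=WINDOW_COLUMNS)


def _na(x: float):
    return None if (x is None or (isinstance(x, float) and math.isnan(x))) else x


def repertoire_frame(records) -> pd.DataFrame:
    rows = []
    for rec in records:
        rows.append(
            {
                "id": rec.id,
                "species": rec.species,
                "cluster": rec.cluster,
                "status": rec.status.value,
                "reason": rec.pseudo_reason.value,
                "stop_site": rec.stop_site,
                "theta_precursor": rec.is_theta_precursor,
                "alpha_mature_motif": rec.motif_flags.get("alpha_mature"),
                "theta_nonapeptide_motif": rec.motif_flags.get("theta_nonapeptide"),
            }
        )
    return pd.DataFrame(rows)


def write_json_sidecar(payload: dict, path, subcommand: str, params: dict) -> None:
    doc = {
        "tool": f"defensinevo {__version__}",
        "subcommand": subcommand,
        "parameters": params,
        **payload,
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
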