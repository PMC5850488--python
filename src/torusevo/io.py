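"""Readers and writers: FASTA, angle/secondary-structure tracks, gapped
alignments, PDB dihedral extraction, model serialization, and fixture
generation.

Native track format: TSV with columns (index, residue, phi, psi, ss);
1-based residue index, angles in radians, "NA" for missing.  8-class
secondary-structure labels are reduced to 3 classes by the mapping
H,G,I → H; E,B → S; everything else → C.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .ctmc import AA_ALPHABET, AA_INDEX, SS_ALPHABET, SS_INDEX
from .hmm import EvolutionaryModel
from .observations import SideObservations
from .siteclass import HiddenState, SiteClass
from .tkf import PairAlignment
from .torus import wrap_array
from .wn import WNParams

MODEL_SCHEMA_VERSION = 1

SS8_TO_SS3 = {"H": "H", "G": "H", "I": "H", "E": "S", "B": "S"}


def reduce_ss_label(label: str) -> str:
    return SS8_TO_SS3.get(label.upper(), "C")


@dataclass
class ProteinRecord:
    """One protein: id, sequence, optional angle and secondary-structure tracks."""

    id: str
    sequence: str
    angles: Optional[np.ndarray] = None  # (n, 2), NaN missing
    ss: Optional[str] = None  # length-n string over {H,S,C}, '.' missing

    def __post_init__(self) -> None:
        n = len(self.sequence)
        if self.angles is not None:
            self.angles = np.asarray(self.angles, dtype=float).reshape(n, 2)
        if self.ss is not None and len(self.ss) != n:
            raise ValueError("secondary-structure track length mismatch")

    def to_side_observations(self, unknown_residue: str = "missing") -> SideObservations:
        """Convert to numeric tracks.  unknown_residue: 'missing' codes
        non-canonical residues as absent; 'error' raises."""
        n = len(self.sequence)
        aa = np.full(n, -1, dtype=int)
        for i, c in enumerate(self.sequence):
            if c in AA_INDEX:
                aa[i] = AA_INDEX[c]
            elif unknown_residue == "error":
                raise ValueError(f"non-canonical residue {c!r} at position {i + 1}")
        x = np.full((n, 2), np.nan) if self.angles is None else self.angles.copy()
        ss = np.full(n, -1, dtype=int)
        if self.ss is not None:
            for i, c in enumerate(self.ss):
                if c in SS_INDEX:
                    ss[i] = SS_INDEX[c]
        return SideObservations(aa, x, ss)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path, unknown_residue: str = "missing") -> list[ProteinRecord]:
    """Read protein sequences; lowercase input is uppercased.  Non-canonical
    residues either raise (unknown_residue='error') or are kept in the
    sequence and treated as missing data downstream."""
    from Bio import SeqIO

    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        for i, c in enumerate(seq):
            if c not in AA_INDEX and c != "-":
                if unknown_residue == "error":
                    raise ValueError(
                        f"non-canonical residue {c!r} at position {i + 1} of {rec.id!r}"
                    )
        records.append(ProteinRecord(id=rec.id, sequence=seq))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(path, records: list[ProteinRecord]) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.id}\n")
            for i in range(0, len(r.sequence), 60):
                fh.write(r.sequence[i:i + 60] + "\n")


def read_alignment_fasta(path) -> tuple[PairAlignment, ProteinRecord, ProteinRecord]:
    """Read a 2-row gapped FASTA alignment."""
    rows = read_fasta(path)
    if len(rows) != 2:
        raise ValueError("pairwise alignment FASTA must contain exactly 2 records")
    aln = PairAlignment.from_gapped(rows[0].sequence, rows[1].sequence)
    a = ProteinRecord(rows[0].id, rows[0].sequence.replace("-", ""))
    b = ProteinRecord(rows[1].id, rows[1].sequence.replace("-", ""))
    return aln, a, b


def write_alignment_fasta(path, aln: PairAlignment, rec_a: ProteinRecord,
                          rec_b: ProteinRecord) -> None:
    row_a, row_b = [], []
    for typ, ia, ib in aln.columns:
        row_a.append(rec_a.sequence[ia - 1] if ia else "-")
        row_b.append(rec_b.sequence[ib - 1] if ib else "-")
    write_fasta(path, [
        ProteinRecord(rec_a.id, "".join(row_a)),
        ProteinRecord(rec_b.id, "".join(row_b)),
    ])


def alignment_to_table(aln: PairAlignment) -> pd.DataFrame:
    return pd.DataFrame(aln.columns, columns=["type", "index_a", "index_b"])


# ---------------------------------------------------------------------------
# tracks


def write_track(path, record: ProteinRecord) -> None:
    rows = []
    for i, res in enumerate(record.sequence):
        phi = psi = None
        if record.angles is not None and np.all(np.isfinite(record.angles[i])):
            phi, psi = record.angles[i]
        ss = record.ss[i] if record.ss is not None and record.ss[i] in SS_INDEX else None
        rows.append({
            "index": i + 1, "residue": res,
            "phi": "NA" if phi is None else f"{phi:.10f}",
            "psi": "NA" if psi is None else f"{psi:.10f}",
            "ss": ss if ss is not None else "NA",
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_track(path, record_id: Optional[str] = None) -> ProteinRecord:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    need = {"index", "residue", "phi", "psi", "ss"}
    if not need.issubset(df.columns):
        raise ValueError(f"track file missing columns {sorted(need - set(df.columns))}")
    if list(df["index"].astype(int)) != list(range(1, len(df) + 1)):
        raise ValueError("track indices must be 1..n")
    seq = "".join(df["residue"])
    angles = np.full((len(df), 2), np.nan)
    for i, (p, q) in enumerate(zip(df["phi"], df["psi"])):
        if p != "NA" and q != "NA":
            angles[i] = wrap_array(np.array([float(p), float(q)]))
    # native labels H/S/C pass through; 8-class labels (G, I, E, B, T, …)
    # are reduced; anything else is missing
    raw = [c if c in SS_INDEX else (reduce_ss_label(c) if c not in ("NA", "") else ".")
           for c in df["ss"]]
    ss = "".join(c if c in SS_INDEX else "." for c in raw)
    return ProteinRecord(record_id or Path(str(path)).stem, seq, angles,
                         ss if set(ss) != {"."} else None)


# ---------------------------------------------------------------------------
# PDB dihedral extraction


def extract_dihedrals(pdb_path, chain: str, model_index: int = 0) -> ProteinRecord:
    """Backbone dihedrals from a PDB file: φ_i = (C_{i−1}, N_i, CA_i, C_i),
    ψ_i = (N_i, CA_i, C_i, N_{i+1}), wrapped to [−π, π).

    Termini and residues with incomplete backbones (or broken chains,
    peptide-bond C–N distance > 2.5 Å) get missing angles; an absent chain
    raises.  Residue identity uses the 3-letter code; unknowns become 'X'.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.Polypeptide import protein_letters_3to1
    from Bio.PDB.vectors import calc_dihedral

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", str(pdb_path))
    model = list(structure)[model_index]
    if chain not in [c.id for c in model]:
        raise ValueError(f"chain {chain!r} not present in {pdb_path}")
    residues = [r for r in model[chain] if r.id[0] == " "]
    if len(residues) < 2:
        raise ValueError("chain has fewer than 2 residues")

    def bb(res):
        return {a: res[a].get_vector() for a in ("N", "CA", "C") if a in res}

    seq = []
    n = len(residues)
    angles = np.full((n, 2), np.nan)
    backs = [bb(r) for r in residues]
    for i, res in enumerate(residues):
        seq.append(protein_letters_3to1.get(res.get_resname().upper(), "X"))
        if len(backs[i]) < 3:
            continue
        if i > 0 and len(backs[i - 1]) == 3:
            gap = (residues[i - 1]["C"].coord - residues[i]["N"].coord)
            if np.linalg.norm(gap) <= 2.5:
                angles[i, 0] = calc_dihedral(
                    backs[i - 1]["C"], backs[i]["N"], backs[i]["CA"], backs[i]["C"]
                )
        if i < n - 1 and "N" in backs[i + 1]:
            gap = (residues[i]["C"].coord - residues[i + 1]["N"].coord)
            if np.linalg.norm(gap) <= 2.5:
                angles[i, 1] = calc_dihedral(
                    backs[i]["N"], backs[i]["CA"], backs[i]["C"], backs[i + 1]["N"]
                )
    angles = np.where(np.isfinite(angles), wrap_array(np.nan_to_num(angles)), np.nan)
    # an angle pair is usable only when both φ and ψ are defined
    incomplete = ~np.all(np.isfinite(angles), axis=1)
    angles[incomplete] = np.nan
    return ProteinRecord(f"{Path(str(pdb_path)).stem}_{chain}", "".join(seq), angles)


# ---------------------------------------------------------------------------
# model serialization


def model_to_dict(model: EvolutionaryModel) -> dict:
    def _sc(sc: SiteClass) -> dict:
        return {
            "aa_equilibrium": sc.aa_equilibrium.tolist(),
            "aa_scale": sc.aa_scale,
            "ss_equilibrium": sc.ss_equilibrium.tolist(),
            "wn": sc.wn.as_dict(),
        }

    return {
        "schema_version": MODEL_SCHEMA_VERSION,
        "aa_alphabet": AA_ALPHABET,
        "ss_alphabet": SS_ALPHABET,
        "states": [
            {
                "class1": _sc(s.class1),
                "class2": _sc(s.class2),
                "class_equilibrium": s.class_equilibrium.tolist(),
                "jump_rate": s.jump_rate,
            }
            for s in model.states
        ],
        "transition": model.transition.tolist(),
        "global_aa_exchangeability": model.global_aa_exchangeability.tolist(),
        "global_ss_exchangeability": model.global_ss_exchangeability.tolist(),
    }


def model_from_dict(d: dict) -> EvolutionaryModel:
    if d.get("schema_version") != MODEL_SCHEMA_VERSION:
        raise ValueError(f"unsupported model schema version {d.get('schema_version')!r}")
    if d.get("aa_alphabet") != AA_ALPHABET or d.get("ss_alphabet") != SS_ALPHABET:
        raise ValueError("alphabet mismatch in model file")

    def _sc(e: dict) -> SiteClass:
        return SiteClass(
            aa_equilibrium=np.array(e["aa_equilibrium"]),
            aa_scale=e["aa_scale"],
            ss_equilibrium=np.array(e["ss_equilibrium"]),
            wn=WNParams.from_dict(e["wn"]),
        )

    states = []
    for s in d["states"]:
        pi = np.array(s["class_equilibrium"])
        if abs(pi.sum() - 1.0) > 1e-8:
            raise ValueError("invariant violated on load: class_equilibrium must sum to 1")
        states.append(HiddenState(_sc(s["class1"]), _sc(s["class2"]), pi, s["jump_rate"]))
    return EvolutionaryModel(
        states,
        np.array(d["transition"]),
        np.array(d["global_aa_exchangeability"]),
        np.array(d["global_ss_exchangeability"]),
    )


def save_model(path, model: EvolutionaryModel) -> None:
    with open(path, "w") as fh:
        json.dump(model_to_dict(model), fh, indent=1)


def load_model(path) -> EvolutionaryModel:
    with open(path) as fh:
        return model_from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# fixture generation


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _record_from_side(side, rec_id: str) -> ProteinRecord:
    seq = "".join(AA_ALPHABET[i] if i >= 0 else "X" for i in side.aa)
    ss = "".join(SS_ALPHABET[i] if i >= 0 else "." for i in side.ss)
    return ProteinRecord(rec_id, seq, side.x, ss if set(ss) != {"."} else None)


def generate_fixtures(outdir, n_pairs: int, t_values, seed: int,
                      model: EvolutionaryModel = None,
                      mean_length: float = 60.0) -> dict:
    """Write a synthetic on-disk dataset (FASTA + tracks + true alignments +
    model + manifest) simulated from the generative model; deterministic
    under the seed."""
    from .datasets import default_tkf92, example_model, simulate_indel_pair
    from .observations import split_sides

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if model is None:
        model = example_model()
    tkf = default_tkf92(mean_length)
    rng = np.random.default_rng(seed)
    t_values = list(t_values)
    manifest = {"seed": seed, "n_pairs": n_pairs, "pairs": []}
    save_model(outdir / "model.json", model)
    for i in range(n_pairs):
        t = float(t_values[i % len(t_values)])
        obs, aln = simulate_indel_pair(model, tkf, t, rng)
        side_a, side_b = split_sides(obs)
        rec_a = _record_from_side(side_a, f"pair{i:03d}_a")
        rec_b = _record_from_side(side_b, f"pair{i:03d}_b")
        stem = outdir / f"pair{i:03d}"
        write_fasta(f"{stem}.fasta", [rec_a, rec_b])
        write_track(f"{stem}_a.track.tsv", rec_a)
        write_track(f"{stem}_b.track.tsv", rec_b)
        write_alignment_fasta(f"{stem}.alignment.fasta", aln, rec_a, rec_b)
        manifest["pairs"].append({
            "id": f"pair{i:03d}", "t": t,
            "len_a": side_a.n_residues, "len_b": side_b.n_residues,
        })
    files = sorted(p for p in outdir.iterdir() if p.name != "manifest.json")
    manifest["checksums"] = {p.name: _sha256(p) for p in files}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
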