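"""Bundled tau construct sequences.

The full-length human tau isoform 4R2N (441 residues) is shipped as a FASTA
fixture; the truncation constructs used for in-vitro binding and droplet work
are derived from it by residue range:

* K18 — the four-repeat microtubule-binding fragment, residues 244-372.
* Delta-tau187 — residues 255-441, expressed with an N-terminal His6 tag.

Residue numbering follows the 441-residue isoform (1-based, inclusive).
"""

from __future__ import annotations

from importlib import resources

from Bio import SeqIO

from .chargecalc import ProteinSpec

HIS6_TAG = "MHHHHHH"


def _load_4r2n_sequence() -> str:
    ref = resources.files("taurna.data").joinpath("tau_constructs.fasta")
    with ref.open() as fh:
        record = next(SeqIO.parse(fh, "fasta"))
    return str(record.seq)


def tau_4r2n() -> ProteinSpec:
    """Full-length human tau (4R2N, residues 1-441)."""
    return ProteinSpec(name="tau_4R2N", sequence=_load_4r2n_sequence())


def k18() -> ProteinSpec:
    """K18 fragment (residues 244-372)."""
    return ProteinSpec(name="K18", sequence=_load_4r2n_sequence()[243:372])


def delta_tau187(tag: str = HIS6_TAG) -> ProteinSpec:
    """Delta-tau187 (residues 255-441) with an N-terminal affinity tag.

    The tag contributes to the construct's molar mass; whether it enters the
    net-charge sum is controlled at charge-computation time (see
    :func:`taurna.chargecalc.net_protein_charge`).
    """
    return ProteinSpec(
        name="dtau187", sequence=_load_4r2n_sequence()[254:441], tag=tag
    )
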