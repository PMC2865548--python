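"""Bundled example data.

The precursor FASTA shipped here is SYNTHETIC: stand-in sequences whose
motif architecture follows the published descriptions of the human opioid
prepropeptides (PENK with seven enkephalin motifs, six YGGFM and one YGGFL;
PDYN with three intact opioid cores and two degenerate relic cores; PNOC
with a single FGGFI core and a core-free nocistatin region; POMC with one
YGGFM core and three melanocortin HFRW motifs), with dibasic cleavage
sites flanking the mature peptides. They are not the database sequences and
must not be treated as biological sequence data; they exist so that the
annotation examples run without network access.
"""

from __future__ import annotations

from importlib import resources

from .align import read_fasta

SYNTHETIC_PRECURSOR_FILE = "synthetic_precursors.fasta"


def load_synthetic_precursors() -> dict[str, str]:
    """Synthetic stand-ins for the four human opioid prepropeptides.

    Keys: ``PENK_synthetic``, ``PDYN_synthetic``, ``PNOC_synthetic``,
    ``POMC_synthetic``.
    """
    ref = resources.files("paralogon") / "data" / SYNTHETIC_PRECURSOR_FILE
    with resources.as_file(ref) as path:
        return read_fasta(path)
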