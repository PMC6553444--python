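"""Bundled worked-example datasets.

Two small excerpts of published plastome alignments of grass tribe Poeae,
each centred on a documented intrastrand-deletion (ISD) event:

* ``load_poeae_psbe_petl_alignment`` — 17 taxa x 80 columns from the
  *psbE*–*petL* intergenic spacer.  *Polypogon fugax* carries a 63 bp
  deletion flanked in reference taxa by the direct repeat ``TCCAAAATTC``.
  *Amelichloa brachychaeta* is the customary outgroup.
* ``load_festuca_psaj_rpl33_alignment`` — 5 *Festuca* accessions x 93
  columns from the *psaJ*–*rpl33* intergenic spacer.  The previously
  published *F. ovina* accession (NC_019649) carries a 78 bp deletion
  flanked by the direct repeat ``AAAAAGAAA``, present in all four other
  rows.

Column coordinates used in the docstrings are 0-based half-open.
"""

from importlib import resources

from ..io import Alignment, read_alignment

#: Outgroup taxon of the psbE-petL excerpt.
POEAE_OUTGROUP = "Amelichloa_brachychaeta"
#: Taxon carrying the 63 bp ISD in the psbE-petL excerpt.
POEAE_ISD_TAXON = "Polypogon_fugax"
#: Taxon carrying the 78 bp ISD in the psaJ-rpl33 excerpt.
FESTUCA_ISD_TAXON = "Festuca_ovina_NC019649"


def _load(name: str) -> Alignment:
    with resources.as_file(
        resources.files(__package__) / "data" / name
    ) as path:
        return read_alignment(path)


def load_poeae_psbe_petl_alignment() -> Alignment:
    """17-taxon, 80-column Poeae alignment excerpt (psbE-petL spacer)."""
    return _load("poeae_psbe_petl.fasta")


def load_festuca_psaj_rpl33_alignment() -> Alignment:
    """5-taxon, 93-column Festuca alignment excerpt (psaJ-rpl33 spacer)."""
    return _load("festuca_psaj_rpl33.fasta")
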