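"""Packaged reference tables.

The detoxification-repertoire table lists, for 12 Coleoptera species, the
number of proteins containing each of eight Pfam domains associated with
detoxification and pesticide resistance, plus the published per-species
repertoire totals. Species abbreviations: Ityp *Ips typographus*, Dpon
*Dendroctonus ponderosae*, Hham *Hypothenemus hampei* (the three
scolytines), Agla *Anoplophora glabripennis*, Tcas *Tribolium castaneum*,
Ldec *Leptinotarsa decemlineata*, Apla *Agrilus planipennis*, Cmac
*Callosobruchus maculatus*, Dvir *Diabrotica virgifera*, Otau *Onthophagus
taurus*, Atum *Aethina tumida*, Nves *Nicrophorus vespilloides*.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

SCOLYTINE_SPECIES = ("Ityp", "Dpon", "Hham")
OTHER_COLEOPTERA = (
    "Agla", "Tcas", "Ldec", "Apla", "Cmac", "Dvir", "Otau", "Atum", "Nves",
)

DETOX_DOMAINS = (
    "Lig_chan", "p450", "GST_N", "GST_C",
    "ABC_tran", "UDPGT", "COesterase", "Inhibitor_I29",
)


def load_detox_domain_counts(drop_total: bool = False) -> pd.DataFrame:
    """Species x domain detoxification-repertoire table.

    Returns a DataFrame indexed by species with a ``guild`` column, the
    eight domain-count columns and the published ``Total`` column. With
    ``drop_total=True`` only the domain counts are returned (guild and
    Total removed), ready for :func:`ipskit.effectsize.compare_species_sets`.
    """
    ref = resources.files("ipskit.data") / "detox_domain_counts.tsv"
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", comment="#", index_col="species")
    if drop_total:
        return df[list(DETOX_DOMAINS)]
    return df
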