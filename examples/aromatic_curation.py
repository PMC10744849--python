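"""Aromatic substructure library and kekulization-insensitive identifiers.

Extracts a benzene fragment from a KCF record, detects it inside the two
alternative kekulizations of o-xylene, and shows that rewriting the matched
ring bonds to the aromatic order collapses both forms to one identifier.
"""

from molharm.aromatics import aromatize, detect_aromatic_substructures, extract_from_kcf
from molharm.coloring import compound_identifier
from molharm.compound import parse_kcf
from molharm.fixtures import benzene_kcf, o_xylene

mgr = extract_from_kcf([parse_kcf(benzene_kcf())])
print(f"fragments in manager: {len(mgr.fragments)} "
      f"({mgr.fragments[0].fragment.n_atoms} atoms)")

k0, k1 = o_xylene("ox", 0), o_xylene("ox", 1)
print(f"raw identifiers equal: {compound_identifier(k0) == compound_identifier(k1)}")

matches = detect_aromatic_substructures(k0, mgr)
print(f"aromatic atoms detected in o-xylene: {sorted(matches[0])}")

a0, a1 = aromatize(k0, mgr), aromatize(k1, mgr)
print(f"identifiers equal after curation: "
      f"{compound_identifier(a0) == compound_identifier(a1)}")
# The two kekulizations of o-xylene are genuinely different labeled graphs
# (the double bond either sits between the substituted carbons or not), so
# without curation they would never harmonize as the same compound.
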