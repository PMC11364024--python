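"""Bundled constants for the SERF1a / NT17 / NT17-polyQ peptide system.

Sequences, extinction coefficients at 214 nm, measured dn/dc values and the
published solvent-displaced volumes for SERF1a and NT17.  Everything here is
overridable at the call site; :func:`builtin_species` only provides
convenient defaults for this peptide family.

Where a displaced volume is published (``volume_A3``) it is used verbatim;
otherwise it is computed as the Jacrot (1976) residue-volume sum from the
sequence.  dn/dc was measured only for SERF1a and NT17; the polyQ peptides
default to 0.185 ml/g, the middle of the measured pair, as peptide dn/dc
varies weakly with composition.
"""

from __future__ import annotations

from .composition import SpeciesSpec, species_from_sequence

SEQUENCES = {
    "SERF1a": "MARGNQRELARQKNMKKTQEISKGKRKEDSLTASQRKQRDSEIMQEKQKAANEKKSMQTREK",
    "NT17": "MATLEKLMKAFESLKSF",
    "Htt-0": "MATLEKLMKAFESLKSFQQQQQQQQQQQQQQYK",
    "Htt-1": "MATLEKLMKAFESLKSFLQQLQQQLQQLQQQYK",
    "Htt-3": "MATLEKLMKAFESLKSFPQQPQQQPQQPQQQYK",
}

#: Molar extinction coefficients at 214 nm, 1/(M cm).
EPS214 = {
    "SERF1a": 64310.0,
    "NT17": 27715.0,
    "Htt-0": 49887.0,
    "Htt-1": 49499.0,
    "Htt-3": 60019.0,
}

#: Specific refractive-index increments, ml/g (measured for SERF1a, NT17).
DNDC = {
    "SERF1a": 0.1847,
    "NT17": 0.1870,
    "Htt-0": 0.185,
    "Htt-1": 0.185,
    "Htt-3": 0.185,
}

#: Published solvent-displaced volumes, cubic angstroms.
PUBLISHED_VOLUME_A3 = {
    "SERF1a": 9719.0,
    "NT17": 3190.0,
}


def builtin_species(name: str, use_published_volume: bool = True) -> SpeciesSpec:
    """Return the bundled :class:`SpeciesSpec` for one of the five peptides."""
    if name not in SEQUENCES:
        raise KeyError(f"unknown species {name!r}; have {sorted(SEQUENCES)}")
    spec = species_from_sequence(name, SEQUENCES[name], EPS214[name], DNDC[name])
    if use_published_volume and name in PUBLISHED_VOLUME_A3:
        spec.V = PUBLISHED_VOLUME_A3[name]
    return spec
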