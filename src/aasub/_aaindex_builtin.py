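"""Embedded default amino-acid property scales.

Each entry holds the published 20 values of one AAIndex record, in PAML
amino-acid order (A R N D C Q E G H I L K M F P S T W Y V), keyed by a short
descriptive name and tagged with its AAIndex accession.  The set covers the
property families relevant to protein structure: hydropathy, contact energy,
backbone flexibility, polarity, net charge, molecular weight, residue volume
and maximum accessible surface area.
"""

# name -> (AAIndex accession, description, 20 values in PAML order)
BUILTIN_SCALES: dict[str, tuple[str, str, list[float]]] = {
    "hydropathy": (
        "KYTJ820101",
        "Hydropathy index (Kyte-Doolittle, 1982)",
        [1.8, -4.5, -3.5, -3.5, 2.5, -3.5, -3.5, -0.4, -3.2, 4.5,
         3.8, -3.9, 1.9, 2.8, -1.6, -0.8, -0.7, -0.9, -1.3, 4.2],
    ),
    "contact_energy": (
        "MIYS990105",
        "Optimized relative partition energies, method D (Miyazawa-Jernigan, 1999)",
        [-0.02, 0.08, 0.10, 0.19, -0.32, 0.15, 0.21, -0.02, -0.02, -0.28,
         -0.32, 0.30, -0.25, -0.33, 0.11, 0.11, 0.05, -0.27, -0.23, -0.23],
    ),
    "flexibility": (
        "BHAR880101",
        "Average flexibility indices (Bhaskaran-Ponnuswamy, 1988)",
        [0.357, 0.529, 0.463, 0.511, 0.346, 0.493, 0.497, 0.544, 0.323, 0.462,
         0.365, 0.466, 0.295, 0.314, 0.509, 0.507, 0.444, 0.305, 0.420, 0.386],
    ),
    "polarity": (
        "GRAR740102",
        "Polarity (Grantham, 1974)",
        [8.1, 10.5, 11.6, 13.0, 5.5, 10.5, 12.3, 9.0, 10.4, 5.2,
         4.9, 11.3, 5.7, 5.2, 8.0, 9.2, 8.6, 5.4, 6.2, 5.9],
    ),
    "net_charge": (
        "KLEP840101",
        "Net charge (Klein et al., 1984)",
        [0.0, 1.0, 0.0, -1.0, 0.0, 0.0, -1.0, 0.0, 0.0, 0.0,
         0.0, 1.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0],
    ),
    "molecular_weight": (
        "FASG760101",
        "Molecular weight (Fasman, 1976)",
        [89.09, 174.20, 132.12, 133.10, 121.15, 146.15, 147.13, 75.07, 155.16, 131.17,
         131.17, 146.19, 149.21, 165.19, 115.13, 105.09, 119.12, 204.24, 181.19, 117.15],
    ),
    "volume": (
        "GRAR740103",
        "Volume (Grantham, 1974)",
        [31.0, 124.0, 56.0, 54.0, 55.0, 85.0, 83.0, 3.0, 96.0, 111.0,
         111.0, 119.0, 105.0, 132.0, 32.5, 32.0, 61.0, 170.0, 136.0, 84.0],
    ),
    "max_asa": (
        "CHOC760101",
        "Residue accessible surface area in tripeptide (Chothia, 1976)",
        [115.0, 225.0, 160.0, 150.0, 135.0, 180.0, 190.0, 75.0, 195.0, 175.0,
         170.0, 200.0, 185.0, 210.0, 145.0, 115.0, 140.0, 255.0, 230.0, 155.0],
    ),
}
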