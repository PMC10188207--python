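"""Published equilibrium parameters of the human FoxP1 constructs.

These are the reported values for the ZIP-lin and ZIP-lin-FKH constructs
(dimerization and DNA-binding dissociation constants, chemical-unfolding free
energies, and sub-ensemble anisotropy fractions).  They serve as the
generating truths for the synthetic fixtures: the generators produce data *at*
these values and the fitting stages must recover them.

m-values and the sub-ensemble rotational-correlation defaults are not printed
per construct in the source tables; the defaults below are chosen so that the
synthetic transitions fall in the reported denaturant ranges (0.5-1.5 M for
the first transition, 2.5-4.5 M for the second) and the per-component
steady-state anisotropies fall in the reported 0.01-0.02 / 0.3-0.35 windows.
"""

from __future__ import annotations

# --- dissociation constants, nM -------------------------------------------
KD_NM = {
    "ZIP-lin": 123.0,                 # dimerization, 0-5000 nM titration
    "ZIP-lin-FKH": 29.0,              # dimerization, 0-200 nM titration
    "ZIP-lin-FKH:DNA": 170.0,         # protein binding to labeled cognate DNA
    "FKH:DNA": 176.0,                 # isolated DNA-binding domain control
    "ZIP-lin-FKH+DNA": 55.0,          # apparent dimerization Kd, DNA present
    "FKH-3DDS": 1000.0,               # isolated FKH domain-swapped dimer (lit.)
}

# --- unfolding free energies, kcal/mol --------------------------------------
DG_KCAL = {
    "ZIP-lin dimer": 10.0,            # N2 = 2U two-state dimer
    "ZIP in ZIP-lin-FKH dimer": 12.0,  # two-state dimer, probe at ZIP
    "FKH step1 (N2=2I)": 12.0,        # three-state dimer, first transition
    "FKH step2 (I=U)": 6.0,           # three-state dimer, second transition
    "FKH-3DDS dimer": 19.0,           # isolated FKH dimer stability (lit.)
    "ZIP-lin monomer total": 4.0,     # three-state monomer, summed
    "ZIP-lin-FKH monomer": 6.0,       # two-state monomer
}

# --- m-values used for synthetic truth, kcal/(mol*M), signed ----------------
M_DIMER = -4.0
M_MONOMER = -1.5

# --- labeled-species concentrations, nM -------------------------------------
LABELED_PROTEIN_NM = 5.0      # titrations use 5 nM labeled protein
UNFOLDING_PTOTAL_NM = 200.0   # dimeric unfolding at 200 nM total protein
DNA_PROBE_NM = 200.0          # labeled DNA in the DNA-binding titration

# --- titration grids, nM -----------------------------------------------------
TITRATION_MAX_NM = {
    "ZIP-lin": 5000.0,
    "ZIP-lin-FKH": 200.0,
    "ZIP-lin-FKH:DNA": 500.0,
    "ZIP-lin-FKH+DNA": 200.0,
}

# --- sub-ensemble anisotropy (DNA-free conditions) ---------------------------
FAST_RHO_FRACTION = 0.70     # population fraction of the fast rotational mode
RHO_FAST_NS = 0.2            # local dye rotation, within 0.1-0.3 ns
RHO_SLOW_NS = 60.0           # global tumbling, within 40-170 ns
R0_FUNDAMENTAL = 0.38
TAU_BODIPY_NS = 4.35         # mean lifetime, within the 4.2-4.5 ns window
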