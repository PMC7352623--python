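"""Acquisition geometry and analysis constants.

These mirror a typical 7T preclinical breast-xenograft protocol: a
28 mm in-plane field of view on a 64 x 64 matrix (0.4375 mm in-plane),
1 mm transaxial slices, three diffusion b-values, a seven-point
inversion-recovery series, and a 12.8 s / 20 min dynamic
contrast-enhanced acquisition with ~2 min of pre-contrast baseline.
"""

FOV_MM = 28.0
MATRIX = 64
N_SLICES = 15
SLICE_THICKNESS_MM = 1.0
IN_PLANE_MM = FOV_MM / MATRIX  # 0.4375 mm

VOXEL_SIZE_MM = (IN_PLANE_MM, IN_PLANE_MM, SLICE_THICKNESS_MM)
VOXEL_VOLUME_MM3 = IN_PLANE_MM * IN_PLANE_MM * SLICE_THICKNESS_MM

B_VALUES = (150.0, 500.0, 800.0)  # s/mm^2

# Inversion-recovery T1 mapping: 7 TIs spanning 250-10000 ms, TR 12 s.
INVERSION_TIMES_MS = (250.0, 500.0, 1000.0, 2000.0, 4000.0, 7000.0, 10000.0)
IR_TR_MS = 12000.0

DCE_DT_S = 12.8
DCE_DURATION_S = 1200.0
PRECONTRAST_S = 120.0

# Physiological bounds for pharmacokinetic/diffusion parameters.
KTRANS_BOUNDS = (0.0, 5.0)   # 1/min
VE_BOUNDS = (0.0, 1.0)       # dimensionless
KEP_BOUNDS = (0.0, 5.0)      # 1/min, open interval for validity
ADC_LOWER = 0.0              # mm^2/s, ADC must be positive where valid

# DWI quality filters: a slice is dropped when more than 20% of its tumor
# voxels fail the monotonic-decay check; a scan is dropped when more than
# half of its slices are dropped.  Both inequalities are strict.
DWI_SLICE_REMOVAL_THRESHOLD = 0.20
DWI_SCAN_REMOVAL_THRESHOLD = 0.50

# Habitat labelling thresholds (MRI): high-vascularity when mean Ktrans or
# kep exceeds these; high-cellularity when mean ADC or ve falls below these.
HV_KTRANS_THRESHOLD = 0.1    # 1/min
HV_KEP_THRESHOLD = 0.5       # 1/min
HC_ADC_THRESHOLD = 1e-3      # mm^2/s
HC_VE_THRESHOLD = 0.3

# Habitat labelling thresholds (histology stain densities).
HV_VESSEL_THRESHOLD = 3.0    # vessel count / unit
HC_NUCLEI_THRESHOLD = 100.0  # nuclei count / unit

# Stain-density neighbourhood ("unit"): 150 um x 150 um around each pixel.
DENSITY_WINDOW_UM = 150.0
HISTOLOGY_PIXEL_UM = 0.5     # 20x brightfield scan

# Treatment-response analysis excludes tumors larger than this at baseline.
VOLUME_EXCLUSION_MM3 = 500.0

# Cluster-number search for the gap statistic.
K_RANGE = (2, 10)
GAP_N_REFS = 50

MSI_N_PERM = 1000
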