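"""Reference parameter tables and default fixed parameters for cohort sampling.

The clinical fit tables that would normally anchor a virtual cohort are not
distributable, so the package ships synthetic reference tables: 30 free-
parameter combinations per disease, selected from a numerical survey of the
model parameter space so that simulated cohorts (i) reach molecular remission
under treatment, (ii) span several orders of magnitude of burden decline, and
(iii) contain a non-degenerate mixture of relapsing and non-relapsing
courses.  Only the patient-specific (free) parameters vary across rows; the
remaining parameters are cohort-wide constants shared with the mechanistic
fitter.
"""

import numpy as np

from .disease_models import AMLParameters, CMLParameters

# ---------------------------------------------------------------------------
# AML: fixed rates (1/day) and capacities (cells)
# ---------------------------------------------------------------------------

AML_FIXED = dict(
    t_QA_H=0.02,   # healthy activation: most healthy stem cells stay quiescent
    t_AQ_H=0.05,   # healthy deactivation back into the protected niche
    p_H=0.30,      # healthy proliferation
    d_H=0.18,      # healthy differentiation out of the stem-cell pool
    t_AQ_L=0.01,   # leukemic deactivation (leukemic cells are mostly active)
    d_L=0.02,      # leukemic differentiation
    K_Q=3e4,       # quiescent niche capacity
    K_A=1e6,       # active niche capacity
    c=0.70,        # chemotherapy kill rate while a cycle runs
)

AML_FREE = ("p_L", "t_QA_L")

# columns: p_L (leukemic proliferation, 1/day), t_QA_L (leukemic activation, 1/day)
AML_BASE = np.array([
    (0.055595, 0.259560),
    (0.055808, 0.265081),
    (0.061056, 0.250177),
    (0.057550, 0.243539),
    (0.026049, 0.098797),
    (0.038179, 0.249519),
    (0.037307, 0.128289),
    (0.054533, 0.217487),
    (0.057638, 0.287961),
    (0.033453, 0.099725),
    (0.056406, 0.247095),
    (0.028603, 0.168531),
    (0.060206, 0.271268),
    (0.053157, 0.204609),
    (0.057476, 0.237708),
    (0.032833, 0.166307),
    (0.035389, 0.095358),
    (0.045182, 0.131329),
    (0.029308, 0.139226),
    (0.056043, 0.256599),
    (0.055031, 0.219247),
    (0.035164, 0.240984),
    (0.033820, 0.138023),
    (0.043360, 0.276914),
    (0.059635, 0.266630),
    (0.052036, 0.220124),
    (0.036227, 0.107747),
    (0.060311, 0.252529),
    (0.058250, 0.203939),
    (0.057302, 0.248791),
])

# bounds of the surveyed box; also used as fitting bounds for the MM predictor
AML_FREE_BOUNDS = {"p_L": (0.02, 0.08), "t_QA_L": (0.05, 0.40)}

# ---------------------------------------------------------------------------
# CML: fixed rates (1/month), capacities (cells) and initial conditions
# ---------------------------------------------------------------------------

CML_FIXED = dict(
    p_Y=1.0,     # maximal proliferation of active leukemic cells
    K_Y=1e6,     # active-cell carrying capacity
    r_Z=100.0,   # baseline immune production (cells/month)
    a=0.5,       # immune decay
    X0=1.5e5,    # quiescent leukemic cells at diagnosis
    Y0=9.5e5,    # active leukemic cells at diagnosis (near carrying capacity)
)

CML_FREE = ("p_XY", "p_YX", "e_TKI", "m", "p_Z", "K_Z", "Z0")

CML_BASE = np.array([
    (0.060911, 0.010920, 1.302840, 0.001145, 354.0976, 5.7796e+05, 361.9648),
    (0.058320, 0.011820, 1.721143, 0.001381, 348.2694, 1.4167e+05, 554.9633),
    (0.030947, 0.014379, 0.621531, 0.004717, 2074.7632, 2.9399e+06, 286.2519),
    (0.088489, 0.015307, 1.227014, 0.001140, 571.7016, 2.6100e+06, 226.5791),
    (0.071891, 0.020022, 1.333596, 0.003640, 618.9909, 2.2534e+06, 105.5922),
    (0.068076, 0.026597, 0.863317, 0.002914, 2348.6449, 1.4553e+05, 131.0785),
    (0.075596, 0.007600, 0.757262, 0.003392, 1986.2874, 9.4254e+05, 105.7296),
    (0.073234, 0.025092, 1.280061, 0.001100, 209.3783, 6.5096e+04, 218.0561),
    (0.039218, 0.025891, 1.141808, 0.000529, 861.4830, 5.6526e+05, 255.9703),
    (0.031617, 0.010945, 1.233776, 0.000546, 2951.4017, 7.7816e+05, 797.5947),
    (0.051980, 0.006596, 1.050878, 0.001874, 684.4331, 1.3334e+06, 95.7113),
    (0.070855, 0.006125, 0.909443, 0.005125, 456.2635, 1.4519e+06, 127.7645),
    (0.080273, 0.009218, 1.815815, 0.000672, 1403.3962, 6.1400e+05, 118.4012),
    (0.061570, 0.012170, 1.512851, 0.001203, 2578.8008, 2.7166e+06, 205.6437),
    (0.059483, 0.016177, 0.935068, 0.002522, 1003.4812, 2.9981e+06, 167.5465),
    (0.081224, 0.005667, 1.214809, 0.004443, 342.3467, 5.8529e+04, 401.7204),
    (0.048754, 0.009899, 1.189780, 0.004801, 2811.0430, 1.8607e+05, 737.7316),
    (0.050860, 0.012769, 1.581388, 0.000702, 2572.0868, 1.3735e+05, 263.8321),
    (0.045977, 0.023462, 0.730741, 0.007404, 2655.9873, 2.3499e+06, 381.3135),
    (0.071599, 0.013699, 0.756347, 0.002282, 657.9454, 1.9292e+06, 328.1768),
    (0.061174, 0.010259, 1.558416, 0.002880, 270.7313, 2.3029e+06, 277.3960),
    (0.050502, 0.012807, 1.450614, 0.001179, 1170.2311, 5.3658e+05, 472.4139),
    (0.030371, 0.008415, 0.689117, 0.004283, 620.3147, 1.4605e+06, 82.7081),
    (0.056595, 0.018729, 0.634770, 0.007872, 419.0649, 1.7346e+06, 403.8774),
    (0.032947, 0.019474, 0.780640, 0.002586, 313.8364, 1.1759e+06, 249.0557),
    (0.036809, 0.007226, 1.232483, 0.002518, 555.8941, 4.9501e+04, 281.9716),
    (0.035098, 0.029480, 1.282970, 0.005116, 1172.0550, 4.9939e+05, 60.2231),
    (0.030220, 0.005364, 1.913475, 0.000803, 1462.1990, 2.4125e+06, 384.8928),
    (0.061776, 0.006886, 0.919634, 0.001047, 2478.7345, 3.8132e+05, 439.0047),
    (0.048096, 0.006772, 1.821901, 0.000980, 903.0208, 2.7856e+06, 191.6927),
])

CML_FREE_BOUNDS = {
    "p_XY": (0.02, 0.12), "p_YX": (0.003, 0.05), "e_TKI": (0.4, 2.5),
    "m": (2e-4, 1.5e-2), "p_Z": (100.0, 5000.0), "K_Z": (1e4, 1e7),
    "Z0": (20.0, 2000.0),
}


def default_aml_parameters(p_L: float, t_QA_L: float) -> AMLParameters:
    return AMLParameters(p_L=p_L, t_QA_L=t_QA_L, **AML_FIXED)


def default_cml_parameters(**free) -> CMLParameters:
    return CMLParameters(**free, **CML_FIXED)
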