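# Published second-order regression coefficient sets, transcribed verbatim
# (decimal commas converted to periods).
#
# Predictor conventions:
#   Morphology models:  P, St, AT, PCE, V  — constituent percentages (0-100).
#     PVE is excluded: its percentage depends on the other constituents.
#     Design: pure quadratic (intercept + linears + squares, no cross terms).
#   Diffusion models:  D_FDP in 1e-9 m^2/s, D_SDP in 1e-11 m^2/s, P1 (share).
#     Design: full second order (cross terms included).
#
# Transcription note: in the fast-diffusivity (d_fast) equation the source
# prints the sixth term as "+ 0.001 * P" where a squared term is expected
# from the design (every other constituent carries its square); it is
# transcribed here as 0.001 * P^2.  The source morphology malignancy
# equation mixes decimal separators; both forms are read as plain decimals.
#
# model	term	value
d_fast	intercept	4.07
d_fast	P	-0.06
d_fast	St	-0.09
d_fast	AT	0.03
d_fast	PCE	0.08
d_fast	V	-0.09
d_fast	P^2	0.001
d_fast	St^2	0.001
d_fast	AT^2	-0.001
d_fast	PCE^2	-0.003
d_fast	V^2	0.005
d_slow	intercept	2.42
d_slow	P	0.03
d_slow	St	-0.07
d_slow	AT	-0.01
d_slow	PCE	-0.13
d_slow	V	0.08
d_slow	P^2	-0.001
d_slow	St^2	0.001
d_slow	AT^2	0.0002
d_slow	PCE^2	0.01
d_slow	V^2	-0.005
p1	intercept	1.05
p1	P	0.02
p1	St	-0.013
p1	AT	-0.02
p1	PCE	0.07
p1	V	-0.02
p1	P^2	-0.0004
p1	St^2	0.00002
p1	AT^2	0.0002
p1	PCE^2	-0.003
p1	V^2	0.004
canp_morphology	intercept	-2.18
canp_morphology	P	0.099
canp_morphology	St	0.031
canp_morphology	AT	-0.004
canp_morphology	PCE	-0.02
canp_morphology	V	0.04
canp_morphology	P^2	-0.001
canp_morphology	St^2	-0.0001
canp_morphology	AT^2	0.0004
canp_morphology	PCE^2	0.001
canp_morphology	V^2	0.0001
canp_diffusion2	intercept	-3.01
canp_diffusion2	D_FDP	8.02
canp_diffusion2	D_SDP	0.84
canp_diffusion2	D_FDP^2	-2.36
canp_diffusion2	D_SDP^2	0.5
canp_diffusion2	D_FDP*D_SDP	-2.78
canp_diffusion3	intercept	2.71
canp_diffusion3	D_FDP	5.69
canp_diffusion3	D_SDP	-0.59
canp_diffusion3	P1	-10.21
canp_diffusion3	D_FDP^2	-1.41
canp_diffusion3	D_SDP^2	0.7
canp_diffusion3	P1^2	1.46
canp_diffusion3	D_FDP*D_SDP	-4.19
canp_diffusion3	D_FDP*P1	4.29
canp_diffusion3	D_SDP*P1	2.75
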