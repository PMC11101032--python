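# Single-pole dispersion parameters per detailed tissue class, 3-10 GHz band.
# Normal-tissue Debye parameters follow the literature convention of a fixed
# 13 ps relaxation time for breast tissues in this band; the three adipose and
# three fibroglandular rows span the low/median/high water-content tertiles.
# The malignant row is a 1-pole Cole-Cole fit from large-scale ex-vivo
# malignant-tissue measurements; it is converted to a band-limited Debye
# equivalent at run time.  Benign tumors carry no row: they are mapped inside
# the fibroglandular envelope.  bound_fraction is the +/- heterogeneity band
# applied to skin and muscle (5%).
# columns: tissue,model,eps_inf,delta_eps,tau_ps,sigma_s,alpha,bound_fraction
tissue,model,eps_inf,delta_eps,tau_ps,sigma_s,alpha,bound_fraction
skin,debye,15.93,23.83,13.0,0.831,0.0,0.05
muscle,debye,21.66,33.24,13.0,0.886,0.0,0.05
fat_low,debye,2.28,0.141,13.0,0.0023,0.0,0.0
fat_median,debye,2.848,1.104,13.0,0.005,0.0,0.0
fat_high,debye,3.987,3.545,13.0,0.08,0.0,0.0
fibroglandular_low,debye,12.99,24.4,13.0,0.397,0.0,0.0
fibroglandular_median,debye,13.81,35.55,13.0,0.738,0.0,0.0
fibroglandular_high,debye,14.2,40.49,13.0,0.824,0.0,0.0
transition,debye,8.489,13.972,13.0,0.2385,0.0,0.0
malignant_tumor,cole_cole,6.749,50.09,10.5,0.794,0.051,0.0
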