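# Canonical parameter set of the working-memory attractor network.
# Potentials/currents in mV, times in s, rates in Hz.

p = 6              # selective populations (= stimuli)
f = 0.05           # coding level
N_E = 1600         # excitatory neurons (p*f*N_E = 480 selective)
N_I = 400          # inhibitory neurons
tau_E = 0.02       # excitatory membrane time constant
tau_I = 0.01       # inhibitory membrane time constant
theta = 20.0       # firing threshold
V_R = 10.0         # reset potential
tau_arp = 0.0025   # absolute refractory period
sigma = 0.75       # fast external-noise amplitude
sigma_BG = 1.0     # quenched SD of background external current
sigma_S = 2.0      # quenched SD of stimulus-evoked current
tau_AMPA = 0.005
tau_NMDA = 0.05
tau_GABA = 0.005
X_E = 0.7          # NMDA charge fraction onto excitatory targets
X_I = 0.002        # NMDA charge fraction onto inhibitory targets
J_EE = 0.025       # EPSP on excitatory
J_IE = 0.0625      # EPSP on inhibitory (2.5 * J_EE)
J_EI = 0.075       # IPSP on excitatory (3 * J_EE)
J_II = 0.1         # IPSP on inhibitory (4 * J_EE)
J_plus = 0.156     # potentiated efficacy within a representation
nu_E_sp = 0.75     # target excitatory spontaneous rate
nu_I_sp = 5.0      # target inhibitory spontaneous rate
dt_spiking = 1e-4
dt_rate = 1e-3
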