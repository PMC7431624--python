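ionotropic glutamate receptor signaling pathway
AMPA glutamate receptor complex
regulation of short-term neuronal synaptic plasticity
dopaminergic synapse
synapse maturation
excitatory postsynaptic potential
parallel fiber to Purkinje cell synapse
synapse organization
regulation of AMPA receptor activity
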