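# Control scenario on the coarse grid: the packaged default scheme,
# 1000 x 6000 um channel, 1000 um activator, gel point 450 nM.
id: control-coarse
preset: control
domain: {dx: 50.0}
shears: [0.0, 1.0, 2.0]
integrator: {end_time: 1200.0}
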