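label,met
stationary,1.3
walking,3.5
running,8.0
driving,1.3
gym_workout,6.0
cycling,7.5
swimming,5.8
yoga,2.5
basketball,6.5
tennis,7.3
hiking,5.3
dancing,4.5
rowing,7.0
stair_climbing,4.0
gardening,3.8
strength_training,5.0
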