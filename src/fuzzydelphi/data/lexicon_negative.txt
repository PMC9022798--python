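bad
poor
worse
worst
inadequate
insufficient
lack
lacking
shortage
shortages
delay
delays
delayed
slow
overcrowded
overcrowding
overwhelmed
fatigue
fatigued
burnout
stress
stressed
stressful
error
errors
mistake
mistakes
unsafe
risk
risky
problem
problems
concern
concerns
fail
failure
failing
dissatisfied
dissatisfaction
negative
compromised
strain
strained
crowded
misunderstanding
misunderstandings
frustrated
frustrating
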