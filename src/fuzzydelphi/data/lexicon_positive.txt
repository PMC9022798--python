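good
great
excellent
effective
efficient
improve
improved
improvement
helpful
adequate
sufficient
timely
satisfied
satisfaction
positive
benefit
beneficial
reliable
safe
safely
strong
useful
valuable
well
better
best
clear
robust
smooth
supportive
capable
quality
success
successful
appropriate
important
critical
essential
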