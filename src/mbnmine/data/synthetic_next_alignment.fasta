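>NExT_syn0 synthetic TBDT N-terminal extension variant
MSKQLIFYEDQPVRVFSSQYGPSMRAPYGMILDMDNQGGQKLGGLYIRDEFIHQKHYCGT
QMTEQLSTSKSLFWQKNIVC
>NExT_syn1 synthetic TBDT N-terminal extension variant
MSLQLIFYEEQPHRVFSSQYGPSMRAPYGMSLDMDNQGGQILGGLYIRDEFIHGKHYCGT
QMTCQLYTSKSLFWQKNIVC
>NExT_syn2 synthetic TBDT N-terminal extension variant
MSKQCIFYEDQPVRVFSWQYGPSKRAPLGMILDMDNQGPQKLYGTYIRTEFIHQKHYCGT
QMTEALSTCKSLKWQKNIVC
>NExT_syn3 synthetic TBDT N-terminal extension variant
MSKRLIFENDHSGRVFSSQVGPSMTAPYAMILDMDNQGMQWNYGLYVGEEFYHQKHYCGT
QMTEQLSRSKWLFWQKNWVC
>NExT_syn4 synthetic TBDT N-terminal extension variant
MSKWLIFEEDLPVKVFSQQMGPSMRADYGCILGPDNQGKQKLGGLYGRDENIHQKGYDGR
QMTIQLKTSKSLLKRKNIVY
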