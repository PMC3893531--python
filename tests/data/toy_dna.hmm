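HMMER3/f [3.4 | Aug 2023]
NAME  toy
LENG  5
MAXL  58
ALPH  DNA
RF    no
MM    no
CONS  yes
CS    no
MAP   yes
DATE  Wed Sep 23 18:14:38 2026
NSEQ  4
EFFN  4.000000
CKSUM 2728127339
STATS LOCAL MSV       -6.1714  0.96395
STATS LOCAL VITERBI   -6.4127  0.96395
STATS LOCAL FORWARD   -1.8693  0.96395
HMM          A        C        G        T   
            m->m     m->i     m->d     i->m     i->i     d->m     d->d
  COMPO   1.25715  1.46098  1.09325  1.90784
          1.38629  1.38629  1.38629  1.38629
          0.03279  4.12713  4.12713  1.46634  0.26236  0.00000        *
      1   0.09846  3.58835  3.37856  3.44116      1 A - - -
          1.38629  1.38629  1.38629  1.38629
          0.03279  4.12713  4.12713  1.46634  0.26236  1.09861  0.40547
      2   3.26153  0.14464  3.42672  2.75134      2 c - - -
          1.38629  1.38629  1.38629  1.38629
          0.19709  4.12713  1.81550  1.46634  0.26236  1.09861  0.40547
      3   2.75162  3.33875  0.15358  3.14509      3 g - - -
          1.38629  1.38629  1.38629  1.38629
          0.23524  3.96858  1.65694  1.46634  0.26236  0.53630  0.87925
      4   2.75162  3.33875  0.15358  3.14509      4 g - - -
          1.38629  1.38629  1.38629  1.38629
          0.03853  3.96858  3.96858  1.46634  0.26236  0.53630  0.87925
      5   1.28416  2.21601  2.28676  0.66849      5 t - - -
          1.38629  1.38629  1.38629  1.38629
          0.01653  4.11087        *  1.46634  0.26236  0.00000        *
//
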